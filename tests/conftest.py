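import numpy as np
import pytest

from wallcomp import (
    FractionSet,
    MonosaccharideProfile,
    StoichiometryConfig,
    WallComposition,
)


def make_profile(fraction, sugars, sample_id="s1", tissue="Col", stage=1, rep=1):
    base = {s: 0.0 for s in
            ("Rha", "Fuc", "Ara", "Xyl", "Man", "Gal", "Glc", "GalA")}
    base.update(sugars)
    return MonosaccharideProfile(
        sample_id=sample_id, tissue=tissue, stage=stage, replicate=rep,
        fraction=fraction, sugars=base,
    )


def make_fraction_set(ao=None, koh=None, residue=None, **meta):
    wall_mass = meta.pop("total_wall_mass", 1000.0)
    return FractionSet(
        sample_id=meta.get("sample_id", "s1"),
        tissue=meta.get("tissue", "Col"),
        stage=meta.get("stage", 1),
        replicate=meta.get("rep", 1),
        profiles={
            "AO": make_profile("AO", ao or {}, **meta),
            "KOH": make_profile("KOH", koh or {}, **meta),
            "RESIDUE": make_profile("RESIDUE", residue or {}, **meta),
        },
        total_wall_mass=wall_mass,
    )


def random_composition(rng: np.random.Generator) -> WallComposition:
    """Random wall composition on the 1000 mg/g basis with >= 20% cellulose."""
    w = rng.dirichlet(np.ones(9))
    scale = 800.0  # leave >= 200 mg/g for cellulose
    classes = dict(
        zip(
            ("hg", "rgI_backbone", "rgI_galactan", "rgI_arabinan",
             "arabinogalactan_pool", "xyloglucan", "mannan", "xylan"),
            (w[:8] * scale),
        )
    )
    classes["cellulose"] = 1000.0 - sum(classes.values())
    return WallComposition(
        **classes, ag_ara_fraction=float(rng.uniform(0.1, 0.9))
    )


@pytest.fixture
def default_cfg():
    return StoichiometryConfig()


@pytest.fixture
def demo_composition():
    """A realistic primary-wall mixture: ~57% pectin, ~12% hemicellulose."""
    return WallComposition(
        hg=330.0,
        rgI_backbone=80.0,
        rgI_galactan=90.0,
        rgI_arabinan=50.0,
        arabinogalactan_pool=20.0,
        xyloglucan=90.0,
        mannan=12.0,
        xylan=18.0,
        cellulose=310.0,
    )
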