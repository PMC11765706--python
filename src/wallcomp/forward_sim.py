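"""Forward models generating synthetic data for all three pipeline branches.

Three generators, all seeded and bit-reproducible:

1. :func:`simulate_fraction_set` / :func:`simulate_cohort` — emit the
   monosaccharide profile that a declared polysaccharide composition would
   produce, split the sugars over the sequential-extraction fractions
   (AO / KOH / residue), and perturb with replicate noise.  With noise off
   this is the exact inverse of the attribution calculus, which gives the
   pipeline a round-trip identity to test against.
2. :func:`simulate_wall_image` — ring-shaped "cell wall" micrographs with a
   known green-channel intensity, decoy red/blue channels and a binary wall
   mask, as fixtures for the fragment-sampling quantification.
3. :func:`simulate_expression_matrix` — negative-binomial count matrices
   with planted fold changes and planted correlated gene blocks, plus the
   ground truth (true folds, truth "padj", block labels) needed to score
   the threshold / clustering / network rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition_io import (
    DEFAULT_WALL_MASS,
    FRACTIONS,
    SUGARS,
    FractionSet,
    MonosaccharideProfile,
    ValidationError,
    fraction_sets_to_table,
)
from .deconvolve import StoichiometryConfig

#: Polysaccharide classes a WallComposition declares (no "unattributed").
COMPOSITION_CLASSES: tuple[str, ...] = (
    "hg",
    "rgI_backbone",
    "rgI_galactan",
    "rgI_arabinan",
    "arabinogalactan_pool",
    "xyloglucan",
    "mannan",
    "xylan",
    "cellulose",
)

#: Green-channel ceiling used throughout the fluorescence branch.
INTENSITY_MAX = 254


@dataclass(frozen=True)
class WallComposition:
    """Declared per-class masses (mg/g); must sum to the closure basis."""

    hg: float = 0.0
    rgI_backbone: float = 0.0
    rgI_galactan: float = 0.0
    rgI_arabinan: float = 0.0
    arabinogalactan_pool: float = 0.0
    xyloglucan: float = 0.0
    mannan: float = 0.0
    xylan: float = 0.0
    cellulose: float = 0.0
    closure_total: float = DEFAULT_WALL_MASS
    #: Ara mass fraction of the arabinogalactan pool (1:1 Ara:Gal default).
    ag_ara_fraction: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return {c: float(getattr(self, c)) for c in COMPOSITION_CLASSES}

    def __post_init__(self) -> None:
        for c, m in self.as_dict().items():
            if m < 0:
                raise ValidationError(f"class {c} has negative mass {m}")
        if not 0.0 <= self.ag_ara_fraction <= 1.0:
            raise ValidationError("ag_ara_fraction must lie in [0, 1]")
        total = sum(self.as_dict().values())
        if abs(total - self.closure_total) > 1e-9 * max(1.0, self.closure_total):
            raise ValidationError(
                f"composition sums to {total!r}, closure basis is "
                f"{self.closure_total!r}"
            )


def _default_release() -> dict[str, tuple[float, float, float]]:
    # pectins chelator-extractable, cross-linking glycans alkali-extractable,
    # with a residual tail released only on TFA hydrolysis of the residue
    return {
        "hg": (0.8, 0.1, 0.1),
        "rgI_backbone": (0.8, 0.1, 0.1),
        "rgI_galactan": (0.7, 0.2, 0.1),
        "rgI_arabinan": (0.7, 0.2, 0.1),
        "arabinogalactan_pool": (0.6, 0.3, 0.1),
        "xyloglucan": (0.05, 0.8, 0.15),
        "mannan": (0.05, 0.7, 0.25),
        "xylan": (0.05, 0.8, 0.15),
        "cellulose": (0.0, 0.0, 0.0),
    }


@dataclass(frozen=True)
class ExtractionModel:
    """Per-class release fractions over (AO, KOH, RESIDUE).

    Non-cellulose rows must sum to 1 (all non-cellulosic sugar is recovered
    across the three hydrolysates); cellulose releases nothing — it is
    TFA-resistant and only ever quantified by difference.
    """

    release: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_release
    )

    def __post_init__(self) -> None:
        for c in COMPOSITION_CLASSES:
            if c not in self.release:
                raise ValidationError(f"release missing class {c}")
            row = self.release[c]
            if len(row) != 3 or any(not 0.0 <= x <= 1.0 for x in row):
                raise ValidationError(f"release[{c}] must be 3 fractions in [0,1]")
            if c == "cellulose":
                if any(x != 0.0 for x in row):
                    raise ValidationError(
                        "cellulose release must be 0 (TFA-resistant)"
                    )
            elif abs(sum(row) - 1.0) > 1e-9:
                raise ValidationError(f"release[{c}] must sum to 1")


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-to-replicate measurement noise on sugar masses."""

    kind: str = "multiplicative_lognormal"
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative_lognormal", "additive_gaussian"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValidationError("noise sd must be >= 0")


def _emit_sugars(
    comp: WallComposition, cfg: StoichiometryConfig
) -> dict[str, dict[str, float]]:
    """Per-class sugar emission (mass units), before fraction splitting."""
    out: dict[str, dict[str, float]] = {}
    ratio = cfg.xxfg_ratio
    coef_sum = sum(ratio.values())
    out["xyloglucan"] = {
        s: comp.xyloglucan * ratio[s] / coef_sum for s in ratio
    }
    r = cfg.rgI_backbone_galA_per_rha
    out["rgI_backbone"] = {
        "Rha": comp.rgI_backbone / (1.0 + r),
        "GalA": comp.rgI_backbone * r / (1.0 + r),
    }
    out["hg"] = {"GalA": comp.hg}
    out["rgI_galactan"] = {"Gal": comp.rgI_galactan}
    out["rgI_arabinan"] = {"Ara": comp.rgI_arabinan}
    out["arabinogalactan_pool"] = {
        "Ara": comp.arabinogalactan_pool * comp.ag_ara_fraction,
        "Gal": comp.arabinogalactan_pool * (1.0 - comp.ag_ara_fraction),
    }
    out["mannan"] = {"Man": comp.mannan}
    out["xylan"] = {"Xyl": comp.xylan}
    out["cellulose"] = {}
    return out


def config_for_composition(
    comp: WallComposition, base: StoichiometryConfig | None = None
) -> StoichiometryConfig:
    """The StoichiometryConfig under which deconvolution inverts ``comp``.

    The Ara/Gal split fractions must equal the share of each sugar that the
    composition actually places in RG-I side chains versus the
    arabinogalactan pool; degenerate shares (no Ara or no Gal at all)
    default to 1.
    """
    base = base or StoichiometryConfig()
    ag_ara = comp.arabinogalactan_pool * comp.ag_ara_fraction
    ag_gal = comp.arabinogalactan_pool - ag_ara
    tot_ara = comp.rgI_arabinan + ag_ara
    tot_gal = comp.rgI_galactan + ag_gal
    return StoichiometryConfig(
        xxfg_ratio=dict(base.xxfg_ratio),
        anchor_policy=base.anchor_policy,
        rgI_backbone_galA_per_rha=base.rgI_backbone_galA_per_rha,
        ara_to_rgI=comp.rgI_arabinan / tot_ara if tot_ara > 0 else 1.0,
        gal_to_rgI=comp.rgI_galactan / tot_gal if tot_gal > 0 else 1.0,
        clip_negative=base.clip_negative,
    )


def simulate_fraction_set(
    comp: WallComposition,
    cfg: StoichiometryConfig | None = None,
    extr: ExtractionModel | None = None,
    noise: NoiseModel | None = None,
    *,
    sample_id: str = "sim",
    tissue: str = "Col",
    stage: int = 1,
    replicate: int = 1,
    rng: np.random.Generator | None = None,
) -> FractionSet:
    """Emit the monosaccharide FractionSet a composition would produce.

    Each class emits its constituent sugars (xyloglucan per the XXFG
    coefficients, RG-I backbone as Rha+GalA per the backbone ratio, ...),
    the emission is distributed over AO/KOH/RESIDUE per the extraction
    model, then perturbed per the noise model.  With noise kind ``none``
    the output is exact and the whole-wall totals equal the non-cellulose
    composition mass.
    """
    cfg = cfg or StoichiometryConfig()
    extr = extr or ExtractionModel()
    noise = noise or NoiseModel(kind="none")
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    emissions = _emit_sugars(comp, cfg)
    per_fraction: dict[str, dict[str, float]] = {
        f: {s: 0.0 for s in SUGARS} for f in FRACTIONS
    }
    for cls, sugars in emissions.items():
        split = extr.release[cls]
        for s, mass in sugars.items():
            for frac, share in zip(FRACTIONS, split):
                per_fraction[frac][s] += mass * share

    profiles = {}
    for frac in FRACTIONS:
        sugars = per_fraction[frac]
        if noise.kind == "multiplicative_lognormal" and noise.sd > 0:
            # lognormal with unit mean: E[exp(N(-s^2/2, s^2))] = 1
            s = noise.sd
            factors = rng.lognormal(-0.5 * s * s, s, size=len(SUGARS))
            sugars = {k: v * f for (k, v), f in zip(sugars.items(), factors)}
        elif noise.kind == "additive_gaussian" and noise.sd > 0:
            eps = rng.normal(0.0, noise.sd, size=len(SUGARS))
            sugars = {k: max(v + e, 0.0) for (k, v), e in zip(sugars.items(), eps)}
        profiles[frac] = MonosaccharideProfile(
            sample_id=sample_id,
            tissue=tissue,
            stage=stage,
            replicate=replicate,
            fraction=frac,
            sugars=sugars,
        )
    return FractionSet(
        sample_id=sample_id,
        tissue=tissue,
        stage=stage,
        replicate=replicate,
        profiles=profiles,
        total_wall_mass=comp.closure_total,
    )


def simulate_cohort(
    design: list[tuple[str, int, WallComposition]],
    n_reps: int = 4,
    noise: NoiseModel | None = None,
    cfg: StoichiometryConfig | None = None,
    extr: ExtractionModel | None = None,
) -> tuple[list[FractionSet], pd.DataFrame]:
    """Replicated factorial design: ``n_reps`` FractionSets per design cell.

    Returns both the FractionSets and the CSV-ready long-format table.
    Reproducible under the noise model's seed.
    """
    if not design:
        raise ValidationError("empty design")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    noise = noise or NoiseModel(kind="none")
    rng = np.random.default_rng(noise.seed)
    sets: list[FractionSet] = []
    for tissue, stage, comp in design:
        for rep in range(1, n_reps + 1):
            sets.append(
                simulate_fraction_set(
                    comp,
                    cfg,
                    extr,
                    noise,
                    sample_id=f"{tissue}{stage}_r{rep}",
                    tissue=tissue,
                    stage=stage,
                    replicate=rep,
                    rng=rng,
                )
            )
    return sets, fraction_sets_to_table(sets)


def simulate_wall_image(
    intensity_wall: float,
    intensity_bg: float,
    wall_thickness_px: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    size: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Ring-shaped synthetic "cell wall" micrograph plus its binary mask.

    The green channel carries ``intensity_wall`` inside the ring and
    ``intensity_bg`` outside, plus clipped Gaussian noise; the red and blue
    channels carry decoy gradients so that channel separation is testable.
    Intensities live on the 0-254 quantification scale.
    """
    for name, v in (("intensity_wall", intensity_wall), ("intensity_bg", intensity_bg)):
        if not 0 <= v <= INTENSITY_MAX:
            raise ValidationError(f"{name} must lie in [0, {INTENSITY_MAX}]")
    if wall_thickness_px < 4:
        raise ValidationError(
            "wall_thickness_px must be >= 4 to host 4x4 fragments"
        )
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    radius = np.hypot(yy - c, xx - c)
    outer = size * 0.4
    inner = outer - wall_thickness_px
    mask = (radius <= outer) & (radius > inner)

    green = np.where(mask, float(intensity_wall), float(intensity_bg))
    if noise_sd > 0:
        green = green + rng.normal(0.0, noise_sd, size=green.shape)
    green = np.clip(green, 0, INTENSITY_MAX)

    red = np.clip(xx / (size - 1) * INTENSITY_MAX, 0, INTENSITY_MAX)
    blue = np.clip(yy / (size - 1) * INTENSITY_MAX, 0, INTENSITY_MAX)
    img = np.stack([red, green, blue], axis=-1).astype(np.uint8)
    return img, mask


@dataclass(frozen=True)
class ExpressionTruth:
    """Ground truth planted by :func:`simulate_expression_matrix`."""

    fold: dict[tuple[str, tuple[str, str]], float]
    padj: pd.DataFrame  # gene x contrast, "truth" adjusted p-values
    blocks: dict[str, int]  # gene -> block id (unplanted genes absent)


def simulate_expression_matrix(
    n_genes: int,
    groups: list[tuple[str, int]],
    deg_spec: list[tuple[int, tuple[str, str], float]] | None = None,
    block_spec: list[tuple[list[int], float]] | None = None,
    baseline: float = 200.0,
    seed: int = 0,
    *,
    dispersion_cv: float = 0.3,
):
    """Negative-binomial count matrix with planted structure.

    ``groups`` is a list of (label, n_samples); ``deg_spec`` plants a fold
    change ``fold`` on gene index ``g`` in the second group of a (label_a,
    label_b) contrast; ``block_spec`` plants blocks of correlated genes,
    each a (gene-index list, target correlation r).  Counts are
    gamma-Poisson with biological coefficient of variation
    ``dispersion_cv``.  Correlated blocks share a per-sample latent factor
    mixed with idiosyncratic noise so pairwise Pearson correlation targets
    ``r``.

    Returns ``(ExpressionMatrix, ExpressionTruth)``; truth padj is 1e-4
    for genes planted at fold != 1 and 1.0 otherwise.
    """
    from .coexpress import ExpressionMatrix

    deg_spec = deg_spec or []
    block_spec = block_spec or []
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    for label, n in groups:
        if n < 2:
            raise ValidationError(
                f"group {label!r} has {n} samples; need >= 2 for tests"
            )
    for _, _, fold in deg_spec:
        if not fold > 0:
            raise ValidationError("planted folds must be > 0")
    seen: set[int] = set()
    for genes, _r in block_spec:
        if seen & set(genes):
            raise ValidationError("block memberships must be disjoint")
        seen |= set(genes)

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    sample_ids: list[str] = []
    sample_group: list[str] = []
    for label, n in groups:
        for rep in range(1, n + 1):
            sample_ids.append(f"{label}_r{rep}")
            sample_group.append(label)
    n_samples = len(sample_ids)
    group_of = np.asarray(sample_group)

    log2_mu = np.full((n_genes, n_samples), np.log2(baseline))
    fold_truth: dict[tuple[str, tuple[str, str]], float] = {}
    for g, (a, b), fold in deg_spec:
        log2_mu[g, group_of == b] += np.log2(fold)
        fold_truth[(gene_ids[g], (a, b))] = fold

    # Biological replicate noise: lognormal with CV = dispersion_cv, then
    # Poisson sampling (a negative-binomial-like mixture).  Correlated
    # blocks share their biological variation: each block draws one latent
    # per sample, and block genes mix it with gene-specific noise at weight
    # sqrt(r) so pairwise Pearson correlation targets r on the count scale
    # (the shared biological CV dominates Poisson noise at the default
    # baseline).
    blocks: dict[str, int] = {}
    z = rng.standard_normal((n_genes, n_samples))
    for bi, (genes, r) in enumerate(block_spec):
        latent = rng.standard_normal(n_samples)
        w = np.sqrt(np.clip(r, 0.0, 1.0))
        for g in genes:
            z[g] = w * latent + np.sqrt(1.0 - w * w) * z[g]
            blocks[gene_ids[g]] = bi

    mu = np.exp2(log2_mu)
    if dispersion_cv > 0:
        s = np.sqrt(np.log1p(dispersion_cv**2))  # lognormal sigma for the CV
        mu = mu * np.exp(s * z - 0.5 * s * s)
    counts = rng.poisson(mu).astype(float)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        sample_groups=dict(zip(sample_ids, sample_group)),
    )
    contrasts = sorted({c for _, c, _ in deg_spec})
    padj = pd.DataFrame(1.0, index=gene_ids, columns=[f"{a}_vs_{b}" for a, b in contrasts])
    for g, (a, b), fold in deg_spec:
        if fold != 1.0:
            padj.loc[gene_ids[g], f"{a}_vs_{b}"] = 1e-4
    truth = ExpressionTruth(fold=fold_truth, padj=padj, blocks=blocks)
    return matrix, truth


__all__ = [
    "COMPOSITION_CLASSES",
    "INTENSITY_MAX",
    "WallComposition",
    "ExtractionModel",
    "NoiseModel",
    "config_for_composition",
    "simulate_fraction_set",
    "simulate_cohort",
    "simulate_wall_image",
    "ExpressionTruth",
    "simulate_expression_matrix",
]
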