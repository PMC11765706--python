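"""Stoichiometric attribution of monosaccharide totals to polysaccharide classes.

The calculus maps whole-wall monosaccharide yields (mg/g dry wall) to the
major polysaccharide classes of a primary plant cell wall:

* **Xyloglucan** is quantified through its XXFG oligosaccharide unit, whose
  residue content is Glc:Xyl:Gal:Fuc = 4:3:1:1.  Fucose occurs only in the
  F unit of xyloglucan among the modelled polymers, so it anchors the sum
  (the ``fucose`` policy); a conservative ``limiting`` policy anchors on
  whichever of the four sugars runs out first.
* **Pectins**: the RG-I backbone alternates rhamnose and galacturonic acid,
  so backbone GalA is taken equal to the rhamnose mass; homogalacturonan is
  the remaining GalA.  Non-xyloglucan arabinose and galactose are split
  between RG-I side chains (arabinan, galactan) and a free
  arabinogalactan pool by configurable fractions.
* **Mannan** is all mannose; **xylan** is the xylose left after xyloglucan.
* **Cellulose** is obtained by difference: the wall-mass basis minus
  everything attributed above (it is never built from measured glucose).

Evaluation order is fixed — xyloglucan first, then pectins, then
mannan/xylan, then cellulose by closure — because the galactose available to
pectin is defined as galactose *after* the xyloglucan deduction.  All
clipping is explicit: impossible attributions are capped and a warning code
recorded; masses are never silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .composition_io import (
    DEFAULT_WALL_MASS,
    FractionSet,
    MonosaccharideProfile,
    ValidationError,
    merge_fraction_sums,
)

#: Residue-proportion coefficients of the XXFG unit.
XXFG_RATIO: dict[str, float] = {"Glc": 4.0, "Xyl": 3.0, "Gal": 1.0, "Fuc": 1.0}

#: Anhydro-residue molar masses (g/mol), for the optional molar mode:
#: the free-sugar mass minus one water per glycosidic bond.
ANHYDRO_MASS: dict[str, float] = {
    "Rha": 146.14,
    "Fuc": 146.14,
    "Ara": 132.12,
    "Xyl": 132.12,
    "Man": 162.14,
    "Gal": 162.14,
    "Glc": 162.14,
    "GalA": 176.12,
    "GlcA": 176.12,
}

_CLOSURE_RTOL = 1e-9


@dataclass(frozen=True)
class StoichiometryConfig:
    """All tunable attribution parameters.

    ``ara_to_rgI`` / ``gal_to_rgI`` are the fractions of non-xyloglucan
    arabinose/galactose assigned to RG-I side chains; the remainder goes to
    the arabinogalactan pool.  Defaults of 1.0 send everything to RG-I —
    the study instead used tissue-specific literature ratios that are not
    printed, so these are deliberately free parameters.
    """

    xxfg_ratio: dict[str, float] = field(default_factory=lambda: dict(XXFG_RATIO))
    anchor_policy: str = "fucose"
    rgI_backbone_galA_per_rha: float = 1.0
    ara_to_rgI: float = 1.0
    gal_to_rgI: float = 1.0
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if self.anchor_policy not in ("fucose", "limiting"):
            raise ValidationError(
                f"anchor_policy must be 'fucose' or 'limiting', "
                f"got {self.anchor_policy!r}"
            )
        if set(self.xxfg_ratio) != set(XXFG_RATIO):
            raise ValidationError(
                f"xxfg_ratio must have keys {sorted(XXFG_RATIO)}"
            )
        for s, c in self.xxfg_ratio.items():
            if not c > 0:
                raise ValidationError(f"xxfg_ratio[{s}] must be > 0, got {c}")
        if self.rgI_backbone_galA_per_rha < 0:
            raise ValidationError("rgI_backbone_galA_per_rha must be >= 0")
        for name in ("ara_to_rgI", "gal_to_rgI"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class PolysaccharideYields:
    """Per-sample polysaccharide-class masses (mg/g dry wall).

    The classes plus ``unattributed`` always sum to ``closure_total``
    (mass closure is an invariant, enforced at construction).
    """

    tissue: str
    stage: int
    replicate: int
    xyloglucan: float
    mannan: float
    xylan: float
    hg: float
    rgI_backbone: float
    rgI_galactan: float
    rgI_arabinan: float
    arabinogalactan_pool: float
    cellulose: float
    unattributed: float
    closure_total: float = DEFAULT_WALL_MASS
    warnings: tuple[str, ...] = ()

    def class_masses(self) -> dict[str, float]:
        return {
            "xyloglucan": self.xyloglucan,
            "mannan": self.mannan,
            "xylan": self.xylan,
            "hg": self.hg,
            "rgI_backbone": self.rgI_backbone,
            "rgI_galactan": self.rgI_galactan,
            "rgI_arabinan": self.rgI_arabinan,
            "arabinogalactan_pool": self.arabinogalactan_pool,
            "cellulose": self.cellulose,
            "unattributed": self.unattributed,
        }

    def __post_init__(self) -> None:
        for name, m in self.class_masses().items():
            if m < 0:
                raise ValidationError(f"class {name} has negative mass {m}")
        total = sum(self.class_masses().values())
        if abs(total - self.closure_total) > _CLOSURE_RTOL * max(
            1.0, self.closure_total
        ):
            raise ValidationError(
                f"mass closure violated: classes sum to {total!r}, "
                f"basis is {self.closure_total!r}"
            )


def attribute_xyloglucan(
    total: MonosaccharideProfile, cfg: StoichiometryConfig
) -> tuple[float, dict[str, float], list[str]]:
    """Quantify xyloglucan from the XXFG residue proportions.

    An anchor unit ``u`` is chosen: under the ``fucose`` policy
    ``u = Fuc / coef_Fuc``, reduced to the limiting sugar's ``mass/coef``
    (with a warning) if the fucose-implied draw would exceed any sugar's
    availability; under the ``limiting`` policy ``u`` is the minimum of
    ``mass/coef`` over the four sugars.  Each sugar's consumed mass is
    ``u * coef``; the xyloglucan yield is their sum (9 mass units per
    anchor unit with the default 4:3:1:1 coefficients).
    """
    ratio = cfg.xxfg_ratio
    warnings: list[str] = []
    limits = {s: total.get(s) / ratio[s] for s in ratio}
    # deterministic order for argmin ties: canonical sugar order
    order = ("Glc", "Xyl", "Gal", "Fuc")
    limiting_sugar = min(order, key=lambda s: limits[s])
    u_limit = limits[limiting_sugar]

    if cfg.anchor_policy == "fucose":
        u = limits["Fuc"]
        if u > u_limit:
            u = u_limit
            warnings.append(f"XYG_LIMITED_BY_{limiting_sugar}")
    else:
        u = u_limit

    consumed = {s: u * ratio[s] for s in order}
    return sum(consumed.values()), consumed, warnings


def attribute_pectin(
    total_after_xyg: MonosaccharideProfile, cfg: StoichiometryConfig
) -> tuple[float, float, float, float, float, list[str]]:
    """Split Rha/GalA/Ara/Gal into HG, RG-I parts and the AG pool.

    Inputs must already have the xyloglucan-consumed masses removed
    (galactose in particular).  Backbone GalA is capped at the measured
    GalA with warning ``RGI_GALA_CLIPPED``.

    Returns (hg, rgI_backbone, rgI_galactan, rgI_arabinan,
    arabinogalactan_pool, warnings).
    """
    warnings: list[str] = []
    rha = total_after_xyg.get("Rha")
    gala = total_after_xyg.get("GalA")
    ara = total_after_xyg.get("Ara")
    gal = total_after_xyg.get("Gal")

    implied = rha * cfg.rgI_backbone_galA_per_rha
    backbone_gala = min(gala, implied)
    if implied > gala:
        warnings.append("RGI_GALA_CLIPPED")
    hg = gala - backbone_gala
    rgI_backbone = rha + backbone_gala
    rgI_arabinan = cfg.ara_to_rgI * ara
    rgI_galactan = cfg.gal_to_rgI * gal
    ag_pool = (ara - rgI_arabinan) + (gal - rgI_galactan)
    return hg, rgI_backbone, rgI_galactan, rgI_arabinan, ag_pool, warnings


def attribute_mannan_xylan(
    total_after_xyg: MonosaccharideProfile,
) -> tuple[float, float]:
    """Mannan = all mannose; xylan = xylose remaining after xyloglucan."""
    return total_after_xyg.get("Man"), total_after_xyg.get("Xyl")


def cellulose_by_difference(
    class_sum: float,
    closure_total: float = DEFAULT_WALL_MASS,
    *,
    clip_negative: bool = True,
) -> tuple[float, list[str]]:
    """Cellulose = wall-mass basis minus everything already attributed.

    If the attributed mass exceeds the basis and ``clip_negative`` is set,
    cellulose is clipped to zero with warning ``CLOSURE_EXCEEDED`` (the
    caller must then shed the overshoot, normally from unattributed mass,
    to restore closure).
    """
    if closure_total <= 0:
        raise ValidationError(f"closure_total must be > 0, got {closure_total}")
    if class_sum < 0:
        raise ValidationError(f"class_sum must be >= 0, got {class_sum}")
    cellulose = closure_total - class_sum
    warnings: list[str] = []
    if cellulose < 0:
        if clip_negative:
            cellulose = 0.0
            warnings.append("CLOSURE_EXCEEDED")
        else:
            raise ValidationError(
                f"attributed mass {class_sum} exceeds basis {closure_total}"
            )
    return cellulose, warnings


def _apply_molar(sugars: dict[str, float]) -> dict[str, float]:
    return {s: m / ANHYDRO_MASS[s] for s, m in sugars.items()}


def deconvolve_sample(
    fs: FractionSet,
    cfg: StoichiometryConfig | None = None,
    *,
    molar: bool = False,
) -> PolysaccharideYields:
    """Run the full attribution calculus on one sample.

    Orchestrates: fraction merge -> xyloglucan -> pectins -> mannan/xylan ->
    cellulose by difference.  Glucuronic acid, non-xyloglucan glucose
    (warning ``FREE_GLC``) and any fucose left by a limiting-sugar clip are
    routed to ``unattributed``.  Mass closure holds exactly.

    With ``molar=True`` the 4:3:1:1 and backbone ratios are applied to
    anhydro-residue molar amounts instead of masses; reported class yields
    are converted back to mg/g so closure is preserved either way.
    """
    cfg = cfg or StoichiometryConfig()
    total = merge_fraction_sums(fs)
    warnings: list[str] = []
    if total.total_mass() == 0:
        warnings.append("EMPTY_PROFILE")

    work = dict(total.sugars)
    if molar:
        work = _apply_molar(work)
    work_profile = lambda: MonosaccharideProfile(  # noqa: E731
        sample_id=total.sample_id,
        tissue=total.tissue,
        stage=total.stage,
        replicate=total.replicate,
        fraction="TOTAL",
        sugars={k: max(v, 0.0) for k, v in work.items()},
    )

    def to_mass(sugar: str, amount: float) -> float:
        return amount * ANHYDRO_MASS[sugar] if molar else amount

    xyg_units, consumed, w = attribute_xyloglucan(work_profile(), cfg)
    warnings.extend(w)
    xyg_mass = sum(to_mass(s, a) for s, a in consumed.items())
    for s, a in consumed.items():
        work[s] = max(work[s] - a, 0.0)

    hg_u, _bb_u, galn_u, arab_u, _ag_u, w = attribute_pectin(work_profile(), cfg)
    warnings.extend(w)
    rha, gala = work["Rha"], work["GalA"]
    backbone_gala = min(gala, rha * cfg.rgI_backbone_galA_per_rha)
    hg = to_mass("GalA", hg_u)
    rgI_backbone = to_mass("Rha", rha) + to_mass("GalA", backbone_gala)
    rgI_galactan = to_mass("Gal", galn_u)
    rgI_arabinan = to_mass("Ara", arab_u)
    ag_pool = to_mass("Ara", work["Ara"] - arab_u) + to_mass(
        "Gal", work["Gal"] - galn_u
    )
    work["Rha"] = work["GalA"] = work["Ara"] = work["Gal"] = 0.0

    man_u, xyl_u = attribute_mannan_xylan(work_profile())
    mannan = to_mass("Man", man_u)
    xylan = to_mass("Xyl", xyl_u)
    work["Man"] = work["Xyl"] = 0.0

    free_glc = to_mass("Glc", work["Glc"])
    if free_glc > 0:
        warnings.append("FREE_GLC")
    leftover_fuc = to_mass("Fuc", work["Fuc"])
    glca = to_mass("GlcA", work.get("GlcA", 0.0))
    unattributed = glca + free_glc + leftover_fuc

    attributed = (
        xyg_mass + mannan + xylan + hg + rgI_backbone + rgI_galactan
        + rgI_arabinan + ag_pool + unattributed
    )
    cellulose, w = cellulose_by_difference(
        attributed, fs.total_wall_mass, clip_negative=cfg.clip_negative
    )
    warnings.extend(w)
    if "CLOSURE_EXCEEDED" in w:
        # shed the overshoot from unattributed mass to restore closure;
        # cannot occur for a valid FractionSet (sugar sum <= wall mass)
        overshoot = attributed - fs.total_wall_mass
        unattributed = max(unattributed - overshoot, 0.0)

    return PolysaccharideYields(
        tissue=fs.tissue,
        stage=fs.stage,
        replicate=fs.replicate,
        xyloglucan=xyg_mass,
        mannan=mannan,
        xylan=xylan,
        hg=hg,
        rgI_backbone=rgI_backbone,
        rgI_galactan=rgI_galactan,
        rgI_arabinan=rgI_arabinan,
        arabinogalactan_pool=ag_pool,
        cellulose=cellulose,
        unattributed=unattributed,
        closure_total=fs.total_wall_mass,
        warnings=tuple(warnings),
    )


def deconvolve_cohort(
    sets: list[FractionSet],
    cfg: StoichiometryConfig | None = None,
    *,
    molar: bool = False,
):
    """Deconvolve a list of samples into a yield table (DataFrame)."""
    import pandas as pd

    rows = []
    for fs in sets:
        y = deconvolve_sample(fs, cfg, molar=molar)
        row: dict[str, object] = {
            "tissue": y.tissue,
            "stage": y.stage,
            "replicate": y.replicate,
        }
        row.update(y.class_masses())
        row["closure_total"] = y.closure_total
        row["warnings"] = ";".join(y.warnings)
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "XXFG_RATIO",
    "ANHYDRO_MASS",
    "StoichiometryConfig",
    "PolysaccharideYields",
    "attribute_xyloglucan",
    "attribute_pectin",
    "attribute_mannan_xylan",
    "cellulose_by_difference",
    "deconvolve_sample",
    "deconvolve_cohort",
]
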