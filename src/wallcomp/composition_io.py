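"""Tabular I/O for monosaccharide profiles and polysaccharide yield tables.

The deconvolution pipeline consumes per-fraction monosaccharide yields
(mg per g of cell-wall dry mass) from a sequential extraction: an ammonium
oxalate step ("AO", pectin-enriched), a 4 M KOH step ("KOH",
hemicellulose-enriched), and the TFA-hydrolysable sugars of the
cellulose-enriched residue ("RESIDUE").  This module defines the in-memory
containers for those data, the long/wide CSV dialects, and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: The eight sugars the attribution calculus uses, in canonical column order.
SUGARS: tuple[str, ...] = ("Rha", "Fuc", "Ara", "Xyl", "Man", "Gal", "Glc", "GalA")

#: Optional ninth sugar, carried through as unattributed mass.
OPTIONAL_SUGARS: tuple[str, ...] = ("GlcA",)

#: Sequential-extraction fraction labels.
FRACTIONS: tuple[str, ...] = ("AO", "KOH", "RESIDUE")

#: Label given to the sugar-wise sum over all three fractions.
TOTAL_FRACTION = "TOTAL"

TISSUES: tuple[str, ...] = ("Col", "Par", "Vas", "CF")
STAGES: tuple[int, ...] = (1, 2)

#: Default mass basis: composition is reported per 1000 mg (1 g) of dry wall.
DEFAULT_WALL_MASS = 1000.0

METADATA_COLUMNS = ("sample_id", "tissue", "stage", "replicate", "fraction")

#: Polysaccharide-class columns of a yield table, fixed by the deconvolution.
YIELD_CLASSES: tuple[str, ...] = (
    "xyloglucan",
    "mannan",
    "xylan",
    "hg",
    "rgI_backbone",
    "rgI_galactan",
    "rgI_arabinan",
    "arabinogalactan_pool",
    "cellulose",
    "unattributed",
)


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class ValidationError(ValueError):
    """A value violates an invariant (negative mass, bad label, closure)."""


class ConflictError(ValueError):
    """Duplicate (sample, fraction) rows in an input table."""


@dataclass(frozen=True)
class MonosaccharideProfile:
    """One fraction of one sample: sugar -> mass (mg/g cell-wall dry mass)."""

    sample_id: str
    tissue: str
    stage: int
    replicate: int
    fraction: str
    sugars: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"unknown tissue {self.tissue!r}; expected one of {TISSUES}"
            )
        if int(self.stage) not in STAGES:
            raise ValidationError(f"stage must be 1 or 2, got {self.stage!r}")
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")
        if self.fraction not in FRACTIONS + (TOTAL_FRACTION,):
            raise ValidationError(
                f"unknown fraction {self.fraction!r}; expected one of {FRACTIONS}"
            )
        missing = [s for s in SUGARS if s not in self.sugars]
        if missing:
            raise SchemaError(f"missing sugar keys: {', '.join(missing)}")
        for name, mass in self.sugars.items():
            if name not in SUGARS + OPTIONAL_SUGARS:
                raise SchemaError(f"unknown sugar column {name!r}")
            if not mass >= 0.0:
                raise ValidationError(f"sugar {name} has negative mass {mass}")

    def total_mass(self) -> float:
        return float(sum(self.sugars.values()))

    def get(self, sugar: str) -> float:
        return float(self.sugars.get(sugar, 0.0))


@dataclass(frozen=True)
class FractionSet:
    """The three fraction profiles of one biological sample."""

    sample_id: str
    tissue: str
    stage: int
    replicate: int
    profiles: dict[str, MonosaccharideProfile]
    total_wall_mass: float = DEFAULT_WALL_MASS

    def __post_init__(self) -> None:
        if set(self.profiles) != set(FRACTIONS):
            missing = sorted(set(FRACTIONS) - set(self.profiles))
            raise ValidationError(
                f"sample {self.sample_id!r}: missing fraction(s) {missing}"
            )
        for frac, prof in self.profiles.items():
            if prof.fraction != frac:
                raise ValidationError(
                    f"profile keyed {frac!r} labelled {prof.fraction!r}"
                )
            meta = (prof.sample_id, prof.tissue, prof.stage, prof.replicate)
            if meta != (self.sample_id, self.tissue, self.stage, self.replicate):
                raise ValidationError(
                    f"fraction {frac} metadata {meta} does not match the set"
                )
        if self.total_wall_mass <= 0:
            raise ValidationError("total_wall_mass must be positive")
        grand = sum(p.total_mass() for p in self.profiles.values())
        if grand > self.total_wall_mass * (1 + 1e-9):
            raise ValidationError(
                f"sample {self.sample_id!r}: summed sugar mass {grand:.3f} "
                f"exceeds the wall-mass basis {self.total_wall_mass:.3f}"
            )


def merge_fraction_sums(fs: FractionSet) -> MonosaccharideProfile:
    """Sugar-wise sum over the three fractions (whole-wall totals).

    The result carries the synthetic fraction label ``TOTAL``.
    """
    keys: list[str] = list(SUGARS)
    for s in OPTIONAL_SUGARS:
        if any(s in p.sugars for p in fs.profiles.values()):
            keys.append(s)
    totals = {
        s: sum(p.sugars.get(s, 0.0) for p in fs.profiles.values()) for s in keys
    }
    return MonosaccharideProfile(
        sample_id=fs.sample_id,
        tissue=fs.tissue,
        stage=fs.stage,
        replicate=fs.replicate,
        fraction=TOTAL_FRACTION,
        sugars=totals,
    )


def _parse_float(raw: object, *, row: int, column: str) -> float:
    if isinstance(raw, str) and "," in raw:
        raise ValidationError(
            f"row {row}, column {column}: decimal comma in {raw!r}; "
            "only dot-decimal numbers are accepted"
        )
    try:
        value = float(raw)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"row {row}, column {column}: cannot parse {raw!r} as a number"
        ) from exc
    if value < 0:
        raise ValidationError(f"row {row}, column {column}: negative value {value}")
    return value


def read_profile_table(
    path,
    *,
    wide: bool = False,
    total_wall_mass: float = DEFAULT_WALL_MASS,
    sep: str = ",",
) -> list[FractionSet]:
    """Read a monosaccharide profile table into FractionSets.

    The canonical dialect is long format: one row per sample x fraction with
    columns sample_id, tissue, stage, replicate, fraction, then the eight
    sugar columns (GlcA optional).  ``wide=True`` accepts one row per sample
    with fraction-prefixed sugar columns like ``AO_Rha``, ``KOH_Rha``, ...

    Raises SchemaError for missing columns, ValidationError for negative or
    unparseable values (citing the offending row), and ConflictError for
    duplicate (sample, fraction) rows.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if wide:
        df = _wide_to_long(df)
    for col in METADATA_COLUMNS + SUGARS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    has_glca = "GlcA" in df.columns

    profiles: dict[tuple[str, str], MonosaccharideProfile] = {}
    meta: dict[str, tuple[str, int, int]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        sample_id = str(rec["sample_id"])
        fraction = str(rec["fraction"])
        if (sample_id, fraction) in profiles:
            raise ConflictError(
                f"duplicate row for sample {sample_id!r}, fraction {fraction!r}"
            )
        sugars = {s: _parse_float(rec[s], row=idx, column=s) for s in SUGARS}
        if has_glca and not pd.isna(rec["GlcA"]):
            sugars["GlcA"] = _parse_float(rec["GlcA"], row=idx, column="GlcA")
        prof = MonosaccharideProfile(
            sample_id=sample_id,
            tissue=str(rec["tissue"]),
            stage=int(rec["stage"]),
            replicate=int(rec["replicate"]),
            fraction=fraction,
            sugars=sugars,
        )
        profiles[(sample_id, fraction)] = prof
        meta.setdefault(sample_id, (prof.tissue, prof.stage, prof.replicate))

    sets: list[FractionSet] = []
    for sample_id, (tissue, stage, replicate) in meta.items():
        found = {f: profiles[(sample_id, f)] for f in FRACTIONS
                 if (sample_id, f) in profiles}
        if set(found) != set(FRACTIONS):
            missing = sorted(set(FRACTIONS) - set(found))
            raise ValidationError(
                f"sample {sample_id!r}: missing fraction(s) {missing}"
            )
        sets.append(
            FractionSet(
                sample_id=sample_id,
                tissue=tissue,
                stage=stage,
                replicate=replicate,
                profiles=found,
                total_wall_mass=total_wall_mass,
            )
        )
    return sets


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    meta_cols = [c for c in METADATA_COLUMNS if c != "fraction"]
    for col in meta_cols:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    rows = []
    for _, rec in df.iterrows():
        for frac in FRACTIONS:
            out = {c: rec[c] for c in meta_cols}
            out["fraction"] = frac
            for s in SUGARS + OPTIONAL_SUGARS:
                col = f"{frac}_{s}"
                if col in df.columns:
                    out[s] = rec[col]
                elif s in SUGARS:
                    raise SchemaError(f"missing required column: {col}")
            rows.append(out)
    return pd.DataFrame(rows)


def fraction_sets_to_table(sets: list[FractionSet]) -> pd.DataFrame:
    """Long-format DataFrame (the canonical CSV dialect) from FractionSets."""
    rows = []
    for fs in sets:
        for frac in FRACTIONS:
            p = fs.profiles[frac]
            row: dict[str, object] = {
                "sample_id": fs.sample_id,
                "tissue": fs.tissue,
                "stage": fs.stage,
                "replicate": fs.replicate,
                "fraction": frac,
            }
            for s in SUGARS:
                row[s] = p.sugars[s]
            if "GlcA" in p.sugars:
                row["GlcA"] = p.sugars["GlcA"]
            rows.append(row)
    return pd.DataFrame(rows)


def write_yield_table(yields: pd.DataFrame, path) -> None:
    """Write a yield table (one row per sample, one column per class) as CSV.

    Round-trips losslessly through :func:`read_yield_table` to float
    precision.  Refuses to write an empty table.
    """
    if yields is None or len(yields) == 0:
        raise ValidationError("refusing to write an empty yield table")
    missing = [c for c in ("tissue", "stage", "replicate") + YIELD_CLASSES
               if c not in yields.columns]
    if missing:
        raise SchemaError(f"yield table missing column(s): {', '.join(missing)}")
    keys = list(zip(yields["tissue"], yields["stage"], yields["replicate"]))
    if len(set(keys)) != len(keys):
        raise ConflictError("duplicate (tissue, stage, replicate) keys")
    out = yields.copy()
    if "warnings" not in out.columns:
        out["warnings"] = ""
    cols = ["tissue", "stage", "replicate", *YIELD_CLASSES, "closure_total",
            "warnings"]
    if "closure_total" not in out.columns:
        out["closure_total"] = DEFAULT_WALL_MASS
    out[cols].to_csv(path, index=False, float_format="%.12g")


def read_yield_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in YIELD_CLASSES if c not in df.columns]
    if missing:
        raise SchemaError(f"yield table missing column(s): {', '.join(missing)}")
    df["warnings"] = df.get("warnings", pd.Series([""] * len(df))).fillna("")
    return df


__all__ = [
    "SUGARS",
    "OPTIONAL_SUGARS",
    "FRACTIONS",
    "TOTAL_FRACTION",
    "TISSUES",
    "STAGES",
    "DEFAULT_WALL_MASS",
    "YIELD_CLASSES",
    "SchemaError",
    "ValidationError",
    "ConflictError",
    "MonosaccharideProfile",
    "FractionSet",
    "merge_fraction_sums",
    "read_profile_table",
    "fraction_sets_to_table",
    "write_yield_table",
    "read_yield_table",
]
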