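"""Tensile-strength computation and treatment comparison for adhesion pull tests.

A trial glues two rigid blocks together, cures for a set time, and pulls them
apart; tensile strength is the failure force divided by the bonded area,
sigma = 1000 * F / A (F in newtons, A in mm^2, sigma in kPa). Trials where the
blocks never bond are recorded with force 0, i.e. 0 kPa. Treatments are
compared with a two-sided permutation test on the difference of group means,
stratified within animals that contributed trials to both groups; this
replaces a mixed-model fit, which raw per-trial data rarely support.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import FormatError

TREATMENTS = (
    "cure10_40kPa",
    "cure60_40kPa",
    "cure60_4kPa",
    "water",
    "proteinaseK",
    "trypsin",
    "reference_poison",
)

# standard brick bonding face used in the assay, mm
BRICK_FACE_MM = (9.6, 15.8)


def rectangle_area_mm2(width_mm: float, height_mm: float) -> float:
    if width_mm <= 0 or height_mm <= 0:
        raise ValueError("dimensions must be positive")
    return width_mm * height_mm


def tensile_strength(force_n: float, area_mm2: float) -> float:
    """Tensile strength in kPa from failure force (N) and bonded area (mm^2)."""
    if area_mm2 <= 0:
        raise ValueError(f"bonded area must be positive, got {area_mm2}")
    if force_n < 0:
        raise ValueError(f"failure force must be non-negative, got {force_n}")
    return 1000.0 * force_n / area_mm2  # N/mm^2 = MPa -> kPa


@dataclass(frozen=True)
class PullTestRecord:
    """One adhesion trial."""

    frog_id: str
    treatment: str
    glue_mass_mg: float
    bonded_area_mm2: float
    failure_force_n: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.bonded_area_mm2 <= 0:
            raise ValueError("bonded area must be positive")
        if self.failure_force_n < 0:
            raise ValueError("failure force must be non-negative")
        if self.glue_mass_mg < 0:
            raise ValueError("glue mass must be non-negative")

    @property
    def tensile_strength_kpa(self) -> float:
        return tensile_strength(self.failure_force_n, self.bonded_area_mm2)


_COLUMNS = ["frog_id", "treatment", "glue_mass_mg", "bonded_area_mm2", "failure_force_n"]


def read_pulltest_tsv(path: str | Path) -> list[PullTestRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        PullTestRecord(
            frog_id=str(row.frog_id),
            treatment=str(row.treatment),
            glue_mass_mg=float(row.glue_mass_mg),
            bonded_area_mm2=float(row.bonded_area_mm2),
            failure_force_n=float(row.failure_force_n),
        )
        for row in df.itertuples()
    ]


def write_pulltest_tsv(records: list[PullTestRecord], path: str | Path) -> None:
    pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in records]).to_csv(
        path, sep="\t", index=False
    )


def group_summary(records: list[PullTestRecord]) -> pd.DataFrame:
    """Per-treatment n, mean and sample SD of tensile strength (kPa).

    SD uses the n-1 denominator and is NaN for singleton groups.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(
        {
            "treatment": [r.treatment for r in records],
            "strength_kpa": [r.tensile_strength_kpa for r in records],
        }
    )
    out = df.groupby("treatment")["strength_kpa"].agg(
        n="count", mean="mean", sd=lambda x: x.std(ddof=1)
    )
    return out.reset_index()


def permutation_test(
    records: list[PullTestRecord],
    treatment_a: str,
    treatment_b: str,
    n_perm: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p for the difference of group mean strengths.

    Labels are shuffled within each animal that contributed trials to both
    treatments (its trials stay its own), and freely among the remaining
    trials. The add-one estimator (1 + exceedances) / (1 + n_perm) never
    returns 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    sel = [r for r in records if r.treatment in (treatment_a, treatment_b)]
    labels = np.array([r.treatment == treatment_a for r in sel])
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise ValueError("both treatment groups must be non-empty")
    values = np.array([r.tensile_strength_kpa for r in sel])
    frogs = np.array([r.frog_id for r in sel])
    dual = {
        f
        for f in set(frogs)
        if labels[frogs == f].any() and (~labels[frogs == f]).any()
    }
    strata = [np.flatnonzero(frogs == f) for f in sorted(dual)]
    rest = np.flatnonzero(~np.isin(frogs, sorted(dual)))
    if rest.size:
        strata.append(rest)
    if rng is None:
        rng = np.random.default_rng(seed)

    def stat(lab: np.ndarray) -> float:
        return abs(values[lab].mean() - values[~lab].mean())

    observed = stat(labels)
    exceed = 0
    perm = labels.copy()
    for _ in range(n_perm):
        for idx in strata:
            perm[idx] = labels[idx][rng.permutation(idx.size)]
        if perm.all() or (~perm).all():
            continue  # degenerate shuffle; cannot form two groups
        if stat(perm) >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)
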