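"""Biomarker screening: fold change, univariate testing, mass annotation.

Two-group metabolite screening: per-metabolite fold change (case-group
mean over control-group mean) with an up/down direction arrow for
significant hits, a Welch two-sample t-test per metabolite with
Benjamini–Hochberg adjustment, and precise-mass annotation of measured
m/z values against a reference table at a ppm tolerance (default 5 ppm,
matching Q-TOF accuracy).

The univariate test and the correction are configurable; a |t|-based
ranking is provided as an explicitly labelled surrogate for external
variable-selection scores that are not implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable

logger = logging.getLogger(__name__)

#: Monoisotopic proton mass (Da), used for adduct-to-neutral conversion.
PROTON_MASS = 1.007276

DEFAULT_PPM_TOL = 5.0


@dataclass(frozen=True)
class BiomarkerRecord:
    metabolite: str
    fold: float  # case mean / control mean, 2 decimals
    direction: str  # up | down | flat ("flat" also for non-significant)
    t_statistic: float
    p_value: float
    p_adjusted: float
    significant: bool

    @classmethod
    def columns(cls) -> list[str]:
        return ["metabolite", "fold", "direction", "t_statistic", "p_value", "p_adjusted", "significant"]

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in self.columns()}


@dataclass(frozen=True)
class MassAnnotation:
    name: str
    measured_mz: float
    adduct: str
    neutral_mass: float  # observed, after adduct correction
    reference_mass: float
    ppm_error: float
    matched: bool


_ADDUCT_SHIFT = {"M+H": -PROTON_MASS, "M-H": +PROTON_MASS, "M": 0.0}


def fold_change(table: AbundanceTable, metabolite: str) -> tuple[float, str]:
    """Fold = mean(case)/mean(control), 2 decimals, plus direction candidate.

    The control group is the first group label in column order (e.g. sham),
    the case group the second (e.g. ischemia).  Missing values stay out of
    the means.  Raises on an all-missing group or a non-positive control
    mean (a ratio needs a positive baseline).
    """
    control, case = table.group_labels
    row = table.data.loc[metabolite]
    a = row[table.samples_of(control)].dropna()
    b = row[table.samples_of(case)].dropna()
    if a.empty or b.empty:
        raise ValueError(f"{metabolite}: a group has no non-missing values")
    if a.mean() <= 0:
        raise ValueError(f"{metabolite}: non-positive control-group mean")
    fold = round(float(b.mean() / a.mean()), 2)
    direction = "up" if fold > 1 else ("down" if fold < 1 else "flat")
    return fold, direction


def screen(
    table: AbundanceTable,
    alpha: float = 0.01,
    fdr_method: str = "fdr_bh",
    test: str = "welch",
) -> list[BiomarkerRecord]:
    """Per-metabolite Welch t-test with multiplicity correction.

    Direction arrows are assigned only to significant records (adjusted
    p < alpha); everything else reports "flat".  A metabolite with zero
    variance in both groups gets p = 1 with a warning.  Records come back
    sorted by adjusted p.
    """
    if test != "welch":
        raise ValueError(f"unsupported test {test!r}")
    control, case = table.group_labels
    names, folds, tstats, pvals = [], [], [], []
    for met in table.metabolites:
        row = table.data.loc[met]
        a = row[table.samples_of(control)].dropna().to_numpy()
        b = row[table.samples_of(case)].dropna().to_numpy()
        fold, _ = fold_change(table, met)
        if np.var(a) == 0 and np.var(b) == 0:
            logger.warning("%s: zero variance in both groups; p set to 1", met)
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(b, a, equal_var=False)
        names.append(met)
        folds.append(fold)
        tstats.append(float(t))
        pvals.append(float(p))
    rejected, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=fdr_method)
    records = []
    for name, fold, t, p, padj, rej in zip(names, folds, tstats, pvals, p_adj, rejected):
        significant = bool(padj < alpha)
        if significant:
            direction = "up" if fold > 1 else ("down" if fold < 1 else "flat")
        else:
            direction = "flat"
        records.append(
            BiomarkerRecord(
                metabolite=name,
                fold=fold,
                direction=direction,
                t_statistic=t,
                p_value=p,
                p_adjusted=float(padj),
                significant=significant,
            )
        )
    records.sort(key=lambda r: (r.p_adjusted, r.metabolite))
    return records


def rank_by_t(records: Sequence[BiomarkerRecord]) -> list[BiomarkerRecord]:
    """Surrogate importance ranking by |t| (largest first).

    This is a plain effect-strength ordering, not a reimplementation of
    any external separation-score method.
    """
    return sorted(records, key=lambda r: (-abs(r.t_statistic), r.metabolite))


def annotate_mass(
    measured_mz: float,
    adduct: str,
    reference: Sequence[tuple[str, float]],
    ppm_tol: float = DEFAULT_PPM_TOL,
) -> list[MassAnnotation]:
    """Match a measured m/z against reference neutral masses.

    The observed neutral mass is the measured m/z corrected for the adduct
    (M+H loses a proton, M−H gains one, M is used as-is); the ppm error is
    (observed − reference)/reference × 1e6 and a candidate matches when
    |ppm| < ppm_tol.  Results are sorted by |ppm|.
    """
    if measured_mz <= 0:
        raise ValueError("measured m/z must be positive")
    if adduct not in _ADDUCT_SHIFT:
        raise ValueError(f"unknown adduct {adduct!r}; choose from {sorted(_ADDUCT_SHIFT)}")
    neutral = measured_mz + _ADDUCT_SHIFT[adduct]
    out = []
    for name, ref_mass in reference:
        if ref_mass <= 0:
            raise ValueError(f"{name}: reference mass must be positive")
        ppm = (neutral - ref_mass) / ref_mass * 1e6
        out.append(
            MassAnnotation(
                name=name,
                measured_mz=measured_mz,
                adduct=adduct,
                neutral_mass=neutral,
                reference_mass=ref_mass,
                ppm_error=ppm,
                matched=bool(abs(ppm) < ppm_tol),
            )
        )
    out.sort(key=lambda a: (abs(a.ppm_error), a.name))
    return out
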