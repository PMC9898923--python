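"""Threshold binarization and descriptive sensitization statistics.

The clinical positivity cut-off of the multiplex assay is 0.31 kU/L; a
patient is *sensitized* to a component when sIgE >= threshold (the boundary
value itself counts as positive).  Downstream analyses operate on the
binary patient x component matrix restricted to patients sensitized to at
least one component, mirroring how such cohorts are reported: component
counts, shares of the sensitized sample, mean +/- SD sIgE among positives,
a child/adult split at 18 years, and sensitization frequency profiles over
paediatric/adult age bands (cut at 1, 3, 6, 12, 18, 25, 36, 44, 60 years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away
from .panel_io import PanelTable

DEFAULT_THRESHOLD = 0.31  # kU/L, assay reference value
DEFAULT_CHILD_CUTOFF = 18.0  # years; child = age < cutoff
DEFAULT_CUTPOINTS = (1.0, 3.0, 6.0, 12.0, 18.0, 25.0, 36.0, 44.0, 60.0)


@dataclass
class SensitizationMatrix:
    """Binary patient x component matrix with ages carried through."""

    patient_ids: np.ndarray
    components: tuple[str, ...]
    values: np.ndarray  # (n, k) of 0/1
    ages: np.ndarray  # (n,) years

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.int8)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.patient_ids), len(self.components)):
            raise ValueError("values must be (n_patients, n_components)")
        if len(self.ages) != len(self.patient_ids):
            raise ValueError("ages must align with patient_ids")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def column_counts(self) -> pd.Series:
        return pd.Series(self.values.sum(axis=0), index=list(self.components), dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.components))


def binarize(table: PanelTable, threshold: float = DEFAULT_THRESHOLD) -> SensitizationMatrix:
    """Binarize a panel: entry 1 iff sIgE >= threshold (inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    conc = table.df[list(table.components)].to_numpy(dtype=float)
    return SensitizationMatrix(
        patient_ids=table.df["id"].astype(str).to_numpy(dtype=object),
        components=tuple(table.components),
        values=(conc >= threshold).astype(np.int8),
        ages=table.df["age"].to_numpy(dtype=float),
    )


def filter_sensitized(m: SensitizationMatrix) -> SensitizationMatrix:
    """Keep exactly the patients positive to at least one component."""
    keep = m.values.sum(axis=1) > 0
    return SensitizationMatrix(
        patient_ids=m.patient_ids[keep],
        components=m.components,
        values=m.values[keep],
        ages=m.ages[keep],
    )


def share(count: int, denom: int) -> float:
    """Percentage ``100*count/denom`` rounded half-away-from-zero to 2 dp."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denom:
        raise ValueError("count must lie in [0, denom]")
    return round_half_away(100.0 * count / denom, 2)


@dataclass(frozen=True)
class AgeBands:
    """Half-open age bands [0,c1), [c1,c2), ..., [c_last, inf)."""

    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS

    def __post_init__(self) -> None:
        cps = tuple(float(c) for c in self.cutpoints)
        if not cps or any(c <= 0 for c in cps) or any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("cutpoints must be positive and strictly increasing")
        object.__setattr__(self, "cutpoints", cps)

    @property
    def labels(self) -> tuple[str, ...]:
        edges = (0.0,) + self.cutpoints
        names = [f"[{_fmt_age(a)},{_fmt_age(b)})" for a, b in zip(edges, edges[1:])]
        names.append(f"[{_fmt_age(edges[-1])},inf)")
        return tuple(names)

    def assign(self, ages: Sequence[float]) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if (ages < 0).any():
            raise ValueError("negative age")
        return np.digitize(ages, self.cutpoints, right=False)


def _fmt_age(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def age_stratify(ages: Sequence[float], bands: AgeBands | None = None) -> np.ndarray:
    """Label each age with the unique half-open band containing it."""
    bands = bands or AgeBands()
    labels = np.asarray(bands.labels, dtype=object)
    return labels[bands.assign(ages)]


@dataclass
class AgeProfile:
    """Sensitization frequency per age band and component.

    ``pct_within_band`` uses the band size as denominator;
    ``pct_of_sample`` uses the full sensitized sample.  Empty bands carry
    NaN (undefined), never 0.
    """

    pct_within_band: pd.DataFrame
    pct_of_sample: pd.DataFrame
    band_sizes: pd.Series


def group_frequency_table(m: SensitizationMatrix, bands: AgeBands | None = None) -> AgeProfile:
    """Per-band, per-component sensitization frequencies (percent)."""
    if m.n == 0:
        raise ValueError("empty matrix")
    bands = bands or AgeBands()
    idx = bands.assign(m.ages)
    labels = list(bands.labels)
    sizes = np.bincount(idx, minlength=len(labels))
    counts = np.zeros((len(labels), len(m.components)))
    np.add.at(counts, idx, m.values.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        within = 100.0 * counts / sizes[:, None]
    within[sizes == 0] = np.nan
    of_sample = 100.0 * counts / m.n
    cols = list(m.components)
    return AgeProfile(
        pct_within_band=pd.DataFrame(within, index=labels, columns=cols),
        pct_of_sample=pd.DataFrame(of_sample, index=labels, columns=cols),
        band_sizes=pd.Series(sizes, index=labels, dtype=int),
    )


@dataclass
class CohortSummary:
    """Per-component counts/shares and sIgE summaries, overall and by age.

    Shares use the whole sensitized sample as denominator for every stratum
    (matching how such cohorts are tabulated); pass
    ``stratum_denominator=True`` to ``cohort_summary`` for within-stratum
    shares instead.  Undefined quantities (e.g. SD of a single value) are
    NaN.
    """

    per_component: pd.DataFrame
    n_total_tested: int
    n_sensitized: int
    n_children: int
    n_adults: int
    child_adult_ratio: float
    mean_tige: float
    mean_tige_children: float
    mean_tige_adults: float
    threshold: float
    child_cutoff: float
    stratum_denominator: bool = False

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            return x

        per_comp = {
            comp: {k: clean(v) for k, v in row.items()}
            for comp, row in self.per_component.to_dict(orient="index").items()
        }
        return {
            "n_total_tested": self.n_total_tested,
            "n_sensitized": self.n_sensitized,
            "n_children": self.n_children,
            "n_adults": self.n_adults,
            "child_adult_ratio": clean(self.child_adult_ratio),
            "mean_tige": clean(self.mean_tige),
            "mean_tige_children": clean(self.mean_tige_children),
            "mean_tige_adults": clean(self.mean_tige_adults),
            "threshold": self.threshold,
            "child_cutoff": self.child_cutoff,
            "stratum_denominator": self.stratum_denominator,
            "per_component": per_comp,
        }


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        return math.nan, math.nan
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else math.nan
    return mean, sd


def cohort_summary(
    table: PanelTable,
    matrix: SensitizationMatrix | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    child_cutoff: float = DEFAULT_CHILD_CUTOFF,
    stratum_denominator: bool = False,
) -> CohortSummary:
    """Summarize a cohort: counts, shares, mean +/- SD sIgE among positives.

    ``matrix`` defaults to ``filter_sensitized(binarize(table, threshold))``.
    Children are ``age < child_cutoff``, adults ``age >= child_cutoff``.
    """
    if matrix is None:
        matrix = filter_sensitized(binarize(table, threshold))
    n_total = table.n
    n_sens = matrix.n
    child = matrix.ages < child_cutoff
    n_children = int(child.sum())
    n_adults = n_sens - n_children

    pos_ids = set(matrix.patient_ids.tolist())
    sub = table.df[table.df["id"].astype(str).isin(pos_ids)].set_index("id")
    sub = sub.loc[[str(p) for p in matrix.patient_ids]]
    conc = sub[list(matrix.components)].to_numpy(dtype=float)
    tige = sub["tIgE"].to_numpy(dtype=float)

    strata = {"all": np.ones(n_sens, dtype=bool), "children": child, "adults": ~child}
    denom = {
        "all": n_sens,
        "children": n_children if stratum_denominator else n_sens,
        "adults": n_adults if stratum_denominator else n_sens,
    }

    rows = []
    for j, comp in enumerate(matrix.components):
        row: dict[str, float] = {}
        pos = matrix.values[:, j] == 1
        for name, mask in strata.items():
            sel = pos & mask
            n_pos = int(sel.sum())
            suffix = "" if name == "all" else f"_{name}"
            row[f"n{suffix}"] = n_pos
            row[f"share{suffix}"] = share(n_pos, denom[name]) if denom[name] > 0 else math.nan
            mean, sd = _mean_sd(conc[sel, j])
            row[f"mean_sige{suffix}"] = mean
            row[f"sd_sige{suffix}"] = sd
        rows.append(row)
    per_component = pd.DataFrame(rows, index=list(matrix.components))

    ratio = round_half_away(n_children / n_adults, 2) if n_adults > 0 else math.nan
    with np.errstate(invalid="ignore"):
        mean_tige = float(np.nanmean(tige)) if n_sens and not np.isnan(tige).all() else math.nan
        mt_child = (
            float(np.nanmean(tige[child]))
            if n_children and not np.isnan(tige[child]).all()
            else math.nan
        )
        mt_adult = (
            float(np.nanmean(tige[~child]))
            if n_adults and not np.isnan(tige[~child]).all()
            else math.nan
        )

    return CohortSummary(
        per_component=per_component,
        n_total_tested=n_total,
        n_sensitized=n_sens,
        n_children=n_children,
        n_adults=n_adults,
        child_adult_ratio=ratio,
        mean_tige=mean_tige,
        mean_tige_children=mt_child,
        mean_tige_adults=mt_adult,
        threshold=threshold,
        child_cutoff=child_cutoff,
        stratum_denominator=stratum_denominator,
    )
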