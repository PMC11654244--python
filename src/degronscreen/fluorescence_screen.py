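"""Per-cell GFP summaries and responsiveness classification.

Each strain is imaged before and after induction of the degron; segmented
cells yield one mean GFP intensity per cell.  A strain's population is
summarized by the geometric mean after removing cells more than two SDs
from the (arithmetic) population mean.  Control strains without GFP define
the autofluorescence band; strains brighter than the brightest control are
analyzed quantitatively for a significant signal reduction after induction
("responsiveness"), while a collapse of the imaged cell count marks
induction-provoked death.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CellSummary",
    "CellPopulation",
    "AutofluorescenceBand",
    "StrainCall",
    "summarize_cells",
    "autofluorescence_band",
    "classify_strain",
    "classify_panel",
    "library_summary",
]

CHANNEL_GFP = "GFP"
CHANNEL_MITO = "mito"
CHANNEL_BRIGHTFIELD = "brightfield"

COND_T0 = "t0"
COND_T30MIN = "t30min"
COND_T24H = "t24h"

STATUS_NOT_VISIBLE = "not_visible"
STATUS_RESPONSIVE = "responsive"
STATUS_IRRESPONSIVE = "irresponsive"
STATUS_DEAD = "dead"
STATUS_MANUAL = "manual_review"


@dataclass(frozen=True)
class CellSummary:
    geo_mean: float
    sd: float
    n: int
    trimmed_all: bool = False  # True when trimming removed everything and the
    # untrimmed summary was reported instead


@dataclass
class CellPopulation:
    """Per-cell mean intensities for one strain / channel / condition."""

    strain_id: str
    channel: str
    condition: str
    intensities: np.ndarray
    summary: CellSummary | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("intensities must be a 1-D vector")
        if self.intensities.size and np.any(self.intensities <= 0):
            raise ValueError("per-cell mean intensities must be strictly positive")

    @property
    def n_raw(self) -> int:
        return int(self.intensities.size)

    def summarize(self, trim_k: float = 2.0) -> CellSummary:
        self.summary = summarize_cells(self.intensities, trim_k=trim_k)
        return self.summary


@dataclass(frozen=True)
class AutofluorescenceBand:
    """Background fluorescence band from GFP-free control strains.

    ``lower``/``upper`` are the control mean -/+ two SDs; a strain is called
    fluorescent only when its geometric mean exceeds ``brightest_control``.
    """

    mean: float
    lower: float
    upper: float
    brightest_control: float


@dataclass
class StrainCall:
    strain_id: str
    fluorescent: bool
    status: str
    effect: float = float("nan")  # after/before geometric-mean ratio
    p_value: float = float("nan")
    p_adj: float = float("nan")


def summarize_cells(
    intensities: Sequence[float] | np.ndarray, trim_k: float = 2.0
) -> CellSummary:
    """Trimmed summary of a per-cell intensity vector.

    One pass: cells outside mean +/- ``trim_k`` * SD (both computed on the
    raw values) are removed; the geometric mean, SD and count of the
    survivors are reported.  If the trim removes everything, the untrimmed
    summary is returned with ``trimmed_all`` set.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty cell population")
    if np.any(x <= 0):
        raise ValueError("intensities must be strictly positive")
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    kept = x[np.abs(x - mu) <= trim_k * sd] if x.size > 1 else x
    trimmed_all = kept.size == 0
    if trimmed_all:
        kept = x
    geo = float(np.exp(np.mean(np.log(kept))))
    ksd = float(np.std(kept, ddof=1)) if kept.size > 1 else 0.0
    return CellSummary(geo_mean=geo, sd=ksd, n=int(kept.size), trimmed_all=trimmed_all)


def autofluorescence_band(
    control_geo_means: Sequence[float] | np.ndarray,
) -> AutofluorescenceBand:
    """Autofluorescence band: control mean with a +/- 2 SD interval."""
    x = np.asarray(control_geo_means, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two control strains for the autofluorescence band")
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return AutofluorescenceBand(
        mean=mu, lower=mu - 2.0 * sd, upper=mu + 2.0 * sd, brightest_control=float(np.max(x))
    )


def _reduction_pvalue(before: np.ndarray, after: np.ndarray) -> float:
    """One-sided Welch test on log intensities for a drop after induction."""
    res = stats.ttest_ind(
        np.log(before), np.log(after), equal_var=False, alternative="greater"
    )
    return float(res.pvalue)


def classify_strain(
    before: CellPopulation,
    after: CellPopulation,
    band: AutofluorescenceBand,
    alpha: float = 0.05,
    min_effect: float = 0.75,
    death_fraction: float = 0.25,
    trim_k: float = 2.0,
    p_adj: float | None = None,
    manual_review: bool = False,
) -> StrainCall:
    """Classify one strain as not_visible / responsive / irresponsive / dead.

    A strain is fluorescent iff its before-induction geometric mean exceeds
    the brightest non-fluorescent control.  Non-fluorescent strains are
    ``not_visible`` (or ``manual_review`` when flagged, mirroring the visual
    examination used for dim organellar strains).  A fluorescent strain whose
    imaged cell count after induction collapses below ``death_fraction`` of
    the before count is ``dead``.  Otherwise it is ``responsive`` when the
    one-sided reduction test on log intensities is significant (adjusted
    p-value < ``alpha``) AND the after/before geometric-mean ratio is below
    ``min_effect``; else ``irresponsive``.

    ``p_adj`` lets a caller supply a multiplicity-adjusted p-value computed
    across the whole strain panel (see :func:`classify_panel`); without it
    the raw p-value is used unadjusted.
    """
    if band is None:
        raise ValueError("an autofluorescence band is required")
    bsum = before.summary or before.summarize(trim_k)
    asum = after.summary or after.summarize(trim_k)

    fluorescent = bsum.geo_mean > band.brightest_control
    if not fluorescent:
        status = STATUS_MANUAL if manual_review else STATUS_NOT_VISIBLE
        return StrainCall(before.strain_id, False, status)

    if after.n_raw < death_fraction * before.n_raw:
        return StrainCall(before.strain_id, True, STATUS_DEAD)

    effect = asum.geo_mean / bsum.geo_mean
    p = _reduction_pvalue(before.intensities, after.intensities)
    padj = p if p_adj is None else p_adj
    responsive = (padj < alpha) and (effect < min_effect)
    status = STATUS_RESPONSIVE if responsive else STATUS_IRRESPONSIVE
    return StrainCall(before.strain_id, True, status, effect=effect, p_value=p, p_adj=padj)


def classify_panel(
    pairs: Sequence[tuple[CellPopulation, CellPopulation]],
    band: AutofluorescenceBand,
    alpha: float = 0.05,
    min_effect: float = 0.75,
    death_fraction: float = 0.25,
    trim_k: float = 2.0,
) -> list[StrainCall]:
    """Classify a panel of strains with Benjamini-Hochberg adjustment.

    Reduction p-values are computed for every fluorescent, surviving strain,
    BH-adjusted across that family, and the adjusted values drive the
    responsive/irresponsive decision.
    """
    prelim = [
        classify_strain(
            b, a, band, alpha=alpha, min_effect=min_effect,
            death_fraction=death_fraction, trim_k=trim_k,
        )
        for b, a in pairs
    ]
    tested = [i for i, c in enumerate(prelim) if np.isfinite(c.p_value)]
    if tested:
        padj = stats.false_discovery_control(
            [prelim[i].p_value for i in tested], method="bh"
        )
        for i, q in zip(tested, padj):
            c = prelim[i]
            c.p_adj = float(q)
            responsive = (c.p_adj < alpha) and (c.effect < min_effect)
            c.status = STATUS_RESPONSIVE if responsive else STATUS_IRRESPONSIVE
    return prelim


def library_summary(calls: Iterable[StrainCall]) -> dict[str, float]:
    """Library-level percentages over the relevant denominators.

    ``pct_responsive_of_fluorescent`` uses surviving fluorescent strains as
    denominator; ``pct_responsive_incl_dead`` counts induction-provoked dead
    strains as responding (their protein was essential) over all fluorescent
    strains including the dead ones.  Both variants are reported because the
    choice of denominator is a convention.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("library_summary needs at least one strain call")
    n_total = len(calls)
    n_fluor = sum(c.fluorescent for c in calls)
    n_dead = sum(c.status == STATUS_DEAD for c in calls)
    n_resp = sum(c.status == STATUS_RESPONSIVE for c in calls)
    n_alive_fluor = n_fluor - n_dead
    return {
        "n_strains": float(n_total),
        "pct_fluorescent": 100.0 * n_fluor / n_total,
        "pct_responsive_of_fluorescent": (
            100.0 * n_resp / n_alive_fluor if n_alive_fluor else float("nan")
        ),
        "pct_responsive_incl_dead": (
            100.0 * (n_resp + n_dead) / n_fluor if n_fluor else float("nan")
        ),
    }
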