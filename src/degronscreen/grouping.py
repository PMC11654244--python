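"""Grouped responsiveness: compartments, translocation mode, abundance bins.

Strain calls are joined to curated metadata (subcellular localization,
mitochondrial subcompartment, co-/post-translational translocation mode,
C-terminus orientation, abundance rank) and the fraction of responsive
strains is reported per group.  Localization categories are collapsed to a
canonical set before grouping (early/late Golgi -> Golgi, nucleolus ->
nucleus, several punctate categories -> "punctate composite").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fluorescence_screen import STATUS_DEAD, STATUS_RESPONSIVE, StrainCall

__all__ = [
    "StrainMetadata",
    "COMPARTMENT_COLLAPSE",
    "collapse_compartment",
    "group_responsiveness",
    "group_ratio",
    "quantile_bins",
    "rank_mito_signal",
]

#: collapsing rules from raw localization category to canonical compartment
COMPARTMENT_COLLAPSE: dict[str, str] = {
    "early Golgi": "Golgi",
    "late Golgi": "Golgi",
    "nucleolus": "nucleus",
    "actin": "punctate composite",
    "endosome": "punctate composite",
    "ER to Golgi": "punctate composite",
    "microtubule": "punctate composite",
    "spindle pole": "punctate composite",
}

#: canonical compartments expected after collapsing; others pass through
#: unchanged with a warning
CANONICAL_COMPARTMENTS = frozenset(
    {
        "cytosol",
        "nucleus",
        "mitochondria",
        "ER",
        "Golgi",
        "vacuole",
        "vacuolar membrane",
        "peroxisome",
        "cell periphery",
        "bud",
        "bud neck",
        "lipid droplet",
        "nuclear periphery",
        "punctate composite",
        "ambiguous",
    }
)

MITO_SUBCOMPARTMENTS = ("matrix", "inner membrane", "intermembrane space", "outer membrane")
TRANSLOCATION_MODES = ("co", "post")
CPRIME_ORIENTATIONS = ("cytosolic", "lumenal")


@dataclass
class StrainMetadata:
    strain_id: str
    localization: str = ""
    compartment: str = ""
    mito_subcompartment: str | None = None
    translocation: str | None = None
    c_prime_orientation: str | None = None
    abundance_rank: int | None = None
    mrna_rank: int | None = None

    def __post_init__(self) -> None:
        if not self.compartment and self.localization:
            self.compartment = collapse_compartment(self.localization)


def collapse_compartment(raw: str) -> str:
    """Map a raw localization category to its canonical compartment.

    Unlisted categories pass through unchanged (with a warning when they are
    not already canonical); the mapping is idempotent.
    """
    out = COMPARTMENT_COLLAPSE.get(raw, raw)
    if out not in CANONICAL_COMPARTMENTS and raw not in COMPARTMENT_COLLAPSE:
        warnings.warn(f"unrecognized localization category {raw!r} kept as is", stacklevel=2)
    return out


def group_responsiveness(
    calls: Sequence[StrainCall],
    metadata: pd.DataFrame | Iterable[StrainMetadata],
    group_by: str,
) -> pd.DataFrame:
    """Responsiveness percentage per metadata group.

    Denominators are fluorescent strains with metadata for ``group_by``;
    ``pct`` excludes induction-dead strains from the denominator while
    ``pct_incl_dead`` counts them as responding (the two conventions seen in
    genome-wide summaries).  Groups with no fluorescent strain are omitted.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.DataFrame([vars(m) for m in metadata])
    if group_by not in metadata.columns:
        raise KeyError(f"unknown metadata field: {group_by}")
    calls_df = pd.DataFrame(
        {
            "strain_id": [c.strain_id for c in calls],
            "fluorescent": [c.fluorescent for c in calls],
            "responsive": [c.status == STATUS_RESPONSIVE for c in calls],
            "dead": [c.status == STATUS_DEAD for c in calls],
        }
    )
    joined = calls_df.merge(metadata[["strain_id", group_by]], on="strain_id", how="inner")
    joined = joined[joined[group_by].notna() & joined["fluorescent"]]
    rows = []
    for group, sub in joined.groupby(group_by, sort=True):
        n = len(sub)
        n_dead = int(sub["dead"].sum())
        n_resp = int(sub["responsive"].sum())
        n_alive = n - n_dead
        rows.append(
            {
                "group": group,
                "n": n,
                "n_responsive": n_resp,
                "n_dead": n_dead,
                "pct": 100.0 * n_resp / n_alive if n_alive else np.nan,
                "pct_incl_dead": 100.0 * (n_resp + n_dead) / n,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "n_responsive", "n_dead", "pct", "pct_incl_dead"])


def group_ratio(groups: pd.DataFrame, a: str, b: str, column: str = "pct") -> float:
    """Ratio of responsiveness percentages between two groups (a over b)."""
    table = groups.set_index("group")[column]
    for g in (a, b):
        if g not in table.index:
            raise KeyError(f"group {g!r} not present")
    pa, pb = float(table[a]), float(table[b])
    if pb == 0:
        return float("nan")
    return pa / pb


def quantile_bins(
    items: Sequence[tuple[str, float]] | Mapping[str, float],
    n_bins: int,
) -> dict[str, int]:
    """Split ranked items into equal-size bins; bin 1 holds the best ranks.

    Items are ordered by rank ascending (rank 1 = most abundant); when the
    count does not divide evenly the remainder goes to the lowest-index
    bins, so bin sizes differ by at most one.  E.g. the 650 genes classified
    essential in the deletion collection split into quintiles of exactly 130.
    """
    pairs = list(items.items()) if isinstance(items, Mapping) else list(items)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > len(pairs):
        raise ValueError(f"cannot split {len(pairs)} items into {n_bins} bins")
    pairs.sort(key=lambda p: (p[1], p[0]))
    base, extra = divmod(len(pairs), n_bins)
    out: dict[str, int] = {}
    idx = 0
    for b in range(1, n_bins + 1):
        size = base + (1 if b <= extra else 0)
        for item_id, _ in pairs[idx : idx + size]:
            out[item_id] = b
        idx += size
    return out


def rank_mito_signal(
    intensities: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Rank strains by MitoTracker intensity, brightest first.

    Dense ranking: ties share the better rank and the next distinct value
    takes the next integer.  The output is ordered by rank, then strain id,
    and is invariant to the input ordering.
    """
    s = pd.Series(dict(intensities), dtype=float)
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("MitoTracker intensities must be finite")
    ranks = s.rank(method="dense", ascending=False).astype(int)
    out = pd.DataFrame(
        {"strain_id": s.index, "mito_intensity": s.to_numpy(), "rank": ranks.to_numpy()}
    )
    return out.sort_values(["rank", "strain_id"], ignore_index=True)
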