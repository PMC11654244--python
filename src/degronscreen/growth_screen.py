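"""Relative-growth scoring and essentiality classification for arrayed colony screens.

The screen grows the arrayed degron library on solid media with and without
the degradation inducer (5-Ph-IAA).  Colony sizes are quantified upstream
(e.g. with SGA tools); this module takes those size grids and computes, per
strain, the induced/uninduced colony-size ratio ("relative growth"), applies
a robust per-plate median normalization, and classifies each strain's
essentiality on each medium.  Because the score is a ratio of colonies grown
at the same plate position, shared positional effects (edge colonies growing
larger, etc.) cancel out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PlateGrid",
    "RelativeGrowth",
    "EssentialityCall",
    "VennPartition",
    "score_relative_growth",
    "normalize_scores",
    "classify_essentiality",
    "media_partition",
    "colony_presence",
]

#: canonical media labels; anything else is carried through as free text
MEDIA_RICH = "rich"
MEDIA_MINIMAL = "minimal"
MEDIA_RESPIRATION = "respiration"

# essentiality classes
CLASS_STRINGENT = "stringent_severe"
CLASS_SEVERE = "severe"
CLASS_MODERATE = "moderate"
CLASS_NONE = "none"
CLASS_ABSENT = "absent"

SEVERE_CLASSES = frozenset({CLASS_STRINGENT, CLASS_SEVERE})


@dataclass
class PlateGrid:
    """One plate's colony sizes, e.g. a 1,536-format (32x48) array.

    ``strain_map`` maps (row, col) positions to strain identifiers; positions
    without an entry are empty wells.  Induced/uninduced plate pairs of the
    same physical array must share their ``strain_map``.
    """

    plate_id: str
    media: str
    induced: bool
    replicate: int
    sizes: np.ndarray
    strain_map: dict[tuple[int, int], str]

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.ndim != 2:
            raise ValueError("plate sizes must be a 2-D rows x cols array")
        if not np.all(np.isfinite(self.sizes)) or np.any(self.sizes < 0):
            raise ValueError("colony sizes must be finite and non-negative")
        nrow, ncol = self.sizes.shape
        for (r, c) in self.strain_map:
            if not (0 <= r < nrow and 0 <= c < ncol):
                raise ValueError(f"strain_map position {(r, c)} outside {self.sizes.shape} grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sizes.shape

    def strain_sizes(self) -> dict[str, float]:
        """Colony size per strain on this plate."""
        return {sid: float(self.sizes[pos]) for pos, sid in self.strain_map.items()}


@dataclass
class RelativeGrowth:
    """Induced/uninduced colony-size ratio for one strain on one medium."""

    strain_id: str
    media: str
    raw_ratio: float
    normalized_score: float
    n_replicates: int
    plate_id: str = ""

    @property
    def absent(self) -> bool:
        """True when the strain did not form a scoreable uninduced colony."""
        return not np.isfinite(self.raw_ratio)


@dataclass
class EssentialityCall:
    strain_id: str
    media: str
    essentiality: str  # one of the CLASS_* labels
    score: float = float("nan")

    @property
    def severe(self) -> bool:
        return self.essentiality in SEVERE_CLASSES


@dataclass
class VennPartition:
    """Exhaustive disjoint partition of per-media hit sets.

    ``regions`` is keyed by the frozenset of media in which a strain is a
    hit; region sets are disjoint and their union is the union of all hit
    sets.  ``exclusive`` gives, per medium, the strains hit only there.
    """

    regions: dict[frozenset, set]
    exclusive: dict[str, set]

    def region(self, *media: str) -> set:
        return self.regions.get(frozenset(media), set())

    @property
    def union_size(self) -> int:
        return sum(len(s) for s in self.regions.values())


def score_relative_growth(
    induced_plates: Sequence[PlateGrid],
    uninduced_plates: Sequence[PlateGrid],
    presence_threshold: float = 50.0,
) -> list[RelativeGrowth]:
    """Per-strain induced/uninduced colony-size ratios.

    Replicate plates of each condition are averaged (arithmetic mean of
    colony sizes) before the ratio is taken.  Plates are paired by medium;
    all plates of one medium must share a strain map.  Strains whose mean
    uninduced size is not above ``presence_threshold`` (arbitrary units, same
    scale as the sizes) did not form a colony without induction and are
    marked absent (NaN ratio) rather than scored.
    """
    if not induced_plates or not uninduced_plates:
        raise ValueError("need at least one plate per condition")

    def by_media(plates: Sequence[PlateGrid], induced: bool) -> dict[str, list[PlateGrid]]:
        groups: dict[str, list[PlateGrid]] = {}
        for p in plates:
            if p.induced != induced:
                raise ValueError(
                    f"plate {p.plate_id} has induced={p.induced}, expected {induced}"
                )
            groups.setdefault(p.media, []).append(p)
        return groups

    ind = by_media(induced_plates, True)
    unind = by_media(uninduced_plates, False)
    if set(ind) != set(unind):
        raise ValueError(f"media mismatch: induced {sorted(ind)} vs uninduced {sorted(unind)}")

    out: list[RelativeGrowth] = []
    for media in sorted(ind):
        plates = ind[media] + unind[media]
        ref_map = plates[0].strain_map
        for p in plates[1:]:
            if p.strain_map != ref_map:
                raise ValueError(
                    f"strain_map mismatch between plates {plates[0].plate_id} and {p.plate_id}"
                )
        plate_id = unind[media][0].plate_id
        n_rep = min(len(ind[media]), len(unind[media]))
        for sid in sorted(set(ref_map.values())):
            pos = [p for p, s in ref_map.items() if s == sid]
            mean_ind = float(np.mean([pl.sizes[q] for pl in ind[media] for q in pos]))
            mean_unind = float(np.mean([pl.sizes[q] for pl in unind[media] for q in pos]))
            if mean_unind <= presence_threshold:
                ratio = float("nan")
            else:
                ratio = mean_ind / mean_unind
            out.append(
                RelativeGrowth(
                    strain_id=sid,
                    media=media,
                    raw_ratio=ratio,
                    normalized_score=ratio,
                    n_replicates=n_rep,
                    plate_id=plate_id,
                )
            )
    return out


def _robust_median(values: np.ndarray, trim_k: float) -> float:
    """Median after removing outliers beyond median +/- trim_k robust SDs.

    The robust SD is 1.4826 * MAD (consistent for a normal sample).  With
    MAD = 0 only the values equal to the median survive, so the factor is
    the median itself.
    """
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    sd = 1.4826 * mad
    kept = values[np.abs(values - med) <= trim_k * sd]
    if kept.size == 0:  # cannot happen: the median itself always survives
        kept = values
    return float(np.median(kept))


def normalize_scores(
    scores: Iterable[RelativeGrowth],
    trim_k: float = 2.0,
    min_group: int = 3,
) -> list[RelativeGrowth]:
    """Divide each score by its plate/media group median (outliers removed).

    After normalization the robust median of each group is 1, which makes
    scores comparable across plates and media.  Groups with fewer than
    ``min_group`` scoreable strains are left unnormalized with a warning.
    """
    scores = list(scores)
    groups: dict[tuple[str, str], list[RelativeGrowth]] = {}
    for s in scores:
        groups.setdefault((s.plate_id, s.media), []).append(s)

    out: list[RelativeGrowth] = []
    for key, members in groups.items():
        finite = np.array([m.raw_ratio for m in members if np.isfinite(m.raw_ratio)])
        if finite.size < min_group:
            warnings.warn(
                f"plate/media group {key}: only {finite.size} scoreable strains; "
                "skipping normalization",
                stacklevel=2,
            )
            factor = 1.0
        else:
            factor = _robust_median(finite, trim_k)
            if factor <= 0:
                warnings.warn(
                    f"plate/media group {key}: non-positive plate median; skipping",
                    stacklevel=2,
                )
                factor = 1.0
        for m in members:
            out.append(
                RelativeGrowth(
                    strain_id=m.strain_id,
                    media=m.media,
                    raw_ratio=m.raw_ratio,
                    normalized_score=m.raw_ratio / factor,
                    n_replicates=m.n_replicates,
                    plate_id=m.plate_id,
                )
            )
    return out


def classify_essentiality(
    scores: Iterable[RelativeGrowth],
    permissive: float = 0.5,
    stringent: float = 0.1,
    moderate: float | None = None,
) -> list[EssentialityCall]:
    """Classify strains by normalized relative growth with strict thresholds.

    score < ``stringent``  -> stringent_severe (implies severe)
    score < ``permissive`` -> severe
    score < ``moderate``   -> moderate (only if a moderate threshold is given)
    otherwise              -> none; non-finite scores -> absent
    """
    if not (0 < stringent < permissive):
        raise ValueError("need 0 < stringent < permissive")
    calls = []
    for s in scores:
        x = s.normalized_score
        if not np.isfinite(x):
            cls = CLASS_ABSENT
        elif x < stringent:
            cls = CLASS_STRINGENT
        elif x < permissive:
            cls = CLASS_SEVERE
        elif moderate is not None and x < moderate:
            cls = CLASS_MODERATE
        else:
            cls = CLASS_NONE
        calls.append(EssentialityCall(s.strain_id, s.media, cls, score=x))
    return calls


def media_partition(hit_sets: Mapping[str, set]) -> VennPartition:
    """Partition hits into disjoint Venn regions across media.

    Every strain in the union of the hit sets lands in exactly one region,
    keyed by the set of media where it is a hit.  The per-media exclusive
    sets feed the GO-slim exclusive-hit ranking.
    """
    if len(hit_sets) < 2:
        raise ValueError("media_partition needs at least two media")
    media = sorted(hit_sets)
    regions: dict[frozenset, set] = {}
    union = set().union(*hit_sets.values())
    for strain in union:
        key = frozenset(m for m in media if strain in hit_sets[m])
        regions.setdefault(key, set()).add(strain)
    exclusive = {m: regions.get(frozenset({m}), set()) for m in media}
    return VennPartition(regions=regions, exclusive=exclusive)


def colony_presence(
    sizes: Sequence[float] | np.ndarray, threshold: float = 50.0
) -> tuple[np.ndarray, float]:
    """Presence flags and survival rate for quantified colonies.

    A colony is present iff its quantification is strictly over ``threshold``
    arbitrary units.  Returns the boolean flags and the survival rate as a
    fraction of attempted positions.
    """
    arr = np.asarray(sizes, dtype=float)
    present = arr > threshold
    rate = float(present.mean()) if arr.size else float("nan")
    return present, rate
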