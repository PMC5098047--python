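"""Hotspot calling, enrichment vs. chance, and disease-variant coincidence.

The hotspot threshold is derived from the score distribution of the most
confidently known MAPs (KFSC >= 11): the largest score such that at least
90% of that subset scores at or above it. Variants join MAPs either exactly
at an observed PTM site (Type-1 coincidence) or through the family alignment
column alone (Type-2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maps import MAP
from .types import FamilyAlignment, VariantRecord

DEFAULT_THRESHOLDS = (0.1, 0.196, 0.35, 0.5)
PATHOGENIC = {"pathogenic", "likely_pathogenic"}
BENIGN = {"benign", "likely_benign"}


def derive_hotspot_threshold(
    maps: list[MAP],
    kfsc_min: int = 11,
    coverage: float = 0.90,
    min_subset: int = 10,
) -> float:
    """Score threshold covering >= ``coverage`` of high-KFSC MAPs.

    Uses lower-value (conservative) interpolation of the empirical
    distribution so the coverage contract holds exactly: with n sorted
    scores the threshold is the floor(n·(1−coverage))-th order statistic.
    """
    scores = np.sort(
        [m.score for m in maps if m.kfsc >= kfsc_min and m.score is not None]
    )
    if len(scores) < min_subset:
        raise ValueError(
            f"only {len(scores)} MAPs with KFSC >= {kfsc_min}; "
            "supply an explicit threshold instead"
        )
    k = math.floor(len(scores) * (1.0 - coverage) + 1e-9)  # guard fp, e.g. 10*(1-0.9)
    return float(scores[k])


@dataclass
class HotspotCall:
    map: MAP
    score: float
    is_hotspot: bool
    category: str | None = None  # ingested annotation (known, U1-A..U4), not computed


def call_hotspots(
    maps: list[MAP],
    threshold: float,
    categories: dict[tuple[str, int], str] | None = None,
) -> list[HotspotCall]:
    """Boolean hotspot call per scored MAP: score >= threshold."""
    calls = []
    for m in maps:
        if m.score is None:
            raise ValueError("maps must be scored before hotspot calling")
        cat = categories.get((m.family_id, m.column)) if categories else None
        calls.append(HotspotCall(m, m.score, m.score >= threshold, cat))
    return calls


def hotspot_summary(calls: list[HotspotCall]) -> pd.DataFrame:
    """Hotspot counts split by known/unknown label (and ingested category)."""
    rows = []
    for known in (True, False):
        sub = [c for c in calls if c.map.known_function == known]
        rows.append(
            {
                "label": "known" if known else "unknown",
                "n_maps": len(sub),
                "n_hotspots": sum(c.is_hotspot for c in sub),
            }
        )
    rows.append(
        {"label": "all", "n_maps": len(calls), "n_hotspots": sum(c.is_hotspot for c in calls)}
    )
    return pd.DataFrame(rows)


def enrichment_vs_random(
    scores: np.ndarray,
    subset: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Observed/expected counts of subset members above score thresholds.

    expected = |subset| · P(score >= t) under independence of subset
    membership and score; ratio undefined (NaN) when expected is 0.
    """
    scores = np.asarray(scores, dtype=float)
    subset = np.asarray(subset).astype(bool)
    if not subset.any():
        raise ValueError("empty subset")
    n = len(scores)
    rows = []
    for t in thresholds:
        above = scores >= t
        observed = int((subset & above).sum())
        expected = subset.sum() * above.sum() / n
        rows.append(
            {
                "threshold": t,
                "observed": observed,
                "expected": expected,
                "ratio": observed / expected if expected > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CoincidenceRecord:
    """One variant joined to one MAP, classed as Type-1 or Type-2."""

    variant: VariantRecord
    map: MAP
    type: int  # 1: variant sits on an observed PTM site; 2: column match only

    @property
    def score(self) -> float | None:
        return self.map.score


def join_variants(
    maps: list[MAP],
    variants: list[VariantRecord],
    alignments: dict[str, FamilyAlignment],
) -> tuple[list[CoincidenceRecord], pd.DataFrame]:
    """Join variants to MAPs by exact alignment-column match.

    A variant matches a MAP when its protein is a family member and its
    native position projects onto the MAP's column. Type-1 when that exact
    (uid, position) carries an observed PTM in the MAP, Type-2 otherwise.
    Unmatched variants are dropped and tallied in the returned report.
    """
    map_index = {(m.family_id, m.column): m for m in maps}
    uid_to_family: dict[str, str] = {}
    for fam_id, aln in alignments.items():
        for uid in aln.uids:
            uid_to_family[uid] = fam_id
    records: list[CoincidenceRecord] = []
    drops = {"uid_not_in_families": 0, "position_on_gap_or_outside": 0, "no_map_at_column": 0}
    for v in variants:
        fam_id = uid_to_family.get(v.uid)
        if fam_id is None:
            drops["uid_not_in_families"] += 1
            continue
        aln = alignments[fam_id]
        try:
            col = aln.column_of(v.uid, v.native_position)
        except KeyError:
            drops["position_on_gap_or_outside"] += 1
            continue
        m = map_index.get((fam_id, col))
        if m is None:
            drops["no_map_at_column"] += 1
            continue
        type1 = any(
            o.uid == v.uid and o.native_position == v.native_position
            for o in m.observations
        )
        records.append(CoincidenceRecord(v, m, 1 if type1 else 2))
    report = pd.DataFrame(
        [{"reason": k, "count": n} for k, n in drops.items() if n > 0]
    )
    return records, report


def pathogenic_benign_summary(
    records: list[CoincidenceRecord], threshold: float
) -> pd.DataFrame:
    """Cross-tabulate records by coincidence type, pooled significance and
    hotspot status.

    Pathogenic pools {pathogenic, likely_pathogenic}; benign pools {benign,
    likely_benign}; other significance classes are excluded.
    """
    rows = []
    for t in (1, 2):
        for cls, pool in (("pathogenic", PATHOGENIC), ("benign", BENIGN)):
            sub = [
                r for r in records if r.type == t and r.variant.significance in pool
            ]
            n_hot = sum(1 for r in sub if r.score is not None and r.score >= threshold)
            rows.append(
                {
                    "type": t,
                    "significance": cls,
                    "n_records": len(sub),
                    "n_hotspot": n_hot,
                }
            )
    return pd.DataFrame(rows)
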