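"""Per-locus EST expression profiles and tissue-specificity calls.

A locus's expression profile is the count of identical ESTs attributed to
it in each tissue (libraries of the same tissue are pooled via the library
manifest).  A locus is tissue-specific when it has more than ``min_copies``
supporting ESTs in total and strictly more than ``min_fraction`` of them
come from a single tissue -- both inequalities strict, so a 9:1 profile
(exactly 90%) is NOT specific and a total of exactly ``min_copies`` copies
is not enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import pandas as pd


@dataclass
class ExpressionProfile:
    locus_id: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class TissueCall:
    locus_id: str
    specific_tissue: Optional[str]
    focal_fraction: float


class UnknownLibraryError(KeyError):
    pass


def count_est_support(
    assignments: pd.DataFrame,
    manifest: pd.DataFrame,
    loci: Optional[Iterable[str]] = None,
) -> Dict[str, ExpressionProfile]:
    """Pool per-locus EST counts over libraries of the same tissue.

    ``assignments`` columns: clone_id, library, locus_id (EST rows only);
    ``manifest`` columns: library, tissue.  An EST citing a library absent
    from the manifest raises :class:`UnknownLibraryError` naming the EST.
    """
    lib2tissue: Mapping[str, str] = dict(zip(manifest.library, manifest.tissue))
    profiles: Dict[str, ExpressionProfile] = {}
    if loci is not None:
        for l in loci:
            profiles[l] = ExpressionProfile(l)
    for row in assignments.itertuples():
        tissue = lib2tissue.get(row.library)
        if tissue is None:
            raise UnknownLibraryError(
                f"EST {row.clone_id} cites unknown library {row.library!r}"
            )
        prof = profiles.setdefault(row.locus_id, ExpressionProfile(row.locus_id))
        prof.counts[tissue] = prof.counts.get(tissue, 0) + 1
    return profiles


def call_tissue_specific(
    profile: ExpressionProfile, min_copies: int = 3, min_fraction: float = 0.9
) -> TissueCall:
    """Specific iff total > min_copies and argmax-tissue share > min_fraction."""
    total = profile.total
    if total == 0:
        return TissueCall(profile.locus_id, None, 0.0)
    tissue, count = max(profile.counts.items(), key=lambda kv: (kv[1], kv[0]))
    frac = count / total
    if total > min_copies and frac > min_fraction:
        return TissueCall(profile.locus_id, tissue, frac)
    return TissueCall(profile.locus_id, None, frac)


def expression_matrix(profiles: Mapping[str, ExpressionProfile],
                      tissues: List[str]) -> pd.DataFrame:
    rows = [
        dict(locus_id=l, **{t: p.counts.get(t, 0) for t in tissues})
        for l, p in sorted(profiles.items())
    ]
    return pd.DataFrame(rows, columns=["locus_id"] + tissues)


def calls_frame(calls: Iterable[TissueCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(locus_id=c.locus_id,
                 specific_tissue=c.specific_tissue or "",
                 focal_fraction=round(c.focal_fraction, 4))
            for c in calls
        ],
        columns=["locus_id", "specific_tissue", "focal_fraction"],
    )
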