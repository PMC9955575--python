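"""Lost/novel cellular-attractor taxonomy.

A cellular attractor (CA) is a set of single-cell states (integer
codes), order discarded.  Pooling the CAs a tissue expresses across the
three asocial regions (ON, OFF, SELF) versus across the social regions
(S1, S2, S3):

- a CA is *lost* if present asocially but never socially;
- a CA is *novel* if present socially but never asocially.

Each novel CA is classified by its state-set overlap with the pooled
asocial CAs: no overlap with any -> ``true_novel``; overlap with exactly
one -> ``modified`` (asocial transients stabilized around an existing
CA; equality is impossible since the CA is novel); overlap with two or
more -> ``combined``.
"""

from __future__ import annotations

from collections import defaultdict
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NovelClass",
    "CACatalogue",
    "diff_catalogues",
    "classify_novel",
    "classify_all_novel",
    "novel_lambda_stats",
]

CA = frozenset  # frozenset[int]


class NovelClass(str, Enum):
    MODIFIED = "modified"
    COMBINED = "combined"
    TRUE_NOVEL = "true_novel"


class CACatalogue:
    """Asocial vs social CA sets for one tissue, with the derived counts."""

    def __init__(self, asocial_set: Iterable[CA], social_set: Iterable[CA]) -> None:
        self.asocial_set = frozenset(frozenset(ca) for ca in asocial_set)
        self.social_set = frozenset(frozenset(ca) for ca in social_set)
        self.lost, self.novel = diff_catalogues(self.asocial_set, self.social_set)

    @property
    def m_asocial(self) -> int:
        return len(self.asocial_set)

    @property
    def m_social(self) -> int:
        return len(self.social_set)

    @property
    def m_lost(self) -> int:
        return len(self.lost)

    @property
    def m_novel(self) -> int:
        return len(self.novel)

    def novel_classes(self) -> dict[CA, NovelClass]:
        return classify_all_novel(self.novel, self.asocial_set)

    def summary(self) -> dict:
        classes = self.novel_classes().values()
        return {
            "M_asocial": self.m_asocial,
            "M_social": self.m_social,
            "M_lost": self.m_lost,
            "M_novel": self.m_novel,
            "novel_modified": sum(c is NovelClass.MODIFIED for c in classes),
            "novel_combined": sum(c is NovelClass.COMBINED for c in classes),
            "novel_true": sum(c is NovelClass.TRUE_NOVEL for c in classes),
        }


def diff_catalogues(
    asocial_set: Iterable[CA], social_set: Iterable[CA]
) -> tuple[frozenset, frozenset]:
    """Set differences by state-set equality: (lost, novel) =
    (asocial \\ social, social \\ asocial)."""
    a = frozenset(frozenset(ca) for ca in asocial_set)
    s = frozenset(frozenset(ca) for ca in social_set)
    return a - s, s - a


def classify_novel(novel: CA, asocial_set: Iterable[CA]) -> NovelClass:
    """Classify one novel CA by overlap with the pooled asocial CAs."""
    novel = frozenset(novel)
    asocial = [frozenset(ca) for ca in asocial_set]
    if novel in asocial:
        raise ValueError("CA is present in the asocial catalogue, not novel")
    overlaps = sum(1 for ca in asocial if novel & ca)
    if overlaps == 0:
        return NovelClass.TRUE_NOVEL
    if overlaps == 1:
        return NovelClass.MODIFIED
    return NovelClass.COMBINED


def classify_all_novel(
    novel_set: Iterable[CA], asocial_set: Iterable[CA]
) -> dict[CA, NovelClass]:
    asocial = [frozenset(ca) for ca in asocial_set]
    return {frozenset(ca): classify_novel(ca, asocial) for ca in novel_set}


def novel_lambda_stats(
    sample_records: Sequence[tuple[float, Mapping[CA, float]]],
    novel_set: Iterable[CA],
) -> pd.DataFrame:
    """Per-lambda expression statistics for a tissue's novel CAs.

    ``sample_records`` holds, for each *social* sample, its lambda and a
    mapping CA -> fraction of cells occupying it.  Returns, per lambda:

    - ``novel_fraction``: fraction of the tissue's M_novel CAs expressed
      in at least one sample at that lambda;
    - ``novel_max_cell_fraction``: largest cell fraction in any single
      novel CA over the samples at that lambda, normalized by the
      tissue-wide maximum.

    An empty frame is returned when the tissue has no novel CAs.
    """
    novel = frozenset(frozenset(ca) for ca in novel_set)
    if not novel:
        return pd.DataFrame(
            columns=["lam", "novel_fraction", "novel_max_cell_fraction"]
        )
    expressed: dict[float, set] = defaultdict(set)
    max_frac: dict[float, float] = defaultdict(float)
    for lam, dist in sample_records:
        lam = float(lam)
        for ca, frac in dist.items():
            ca = frozenset(ca)
            if ca in novel and frac > 0:
                expressed[lam].add(ca)
                max_frac[lam] = max(max_frac[lam], float(frac))
    lams = sorted(set(float(lam) for lam, _ in sample_records))
    overall = max(max_frac.values(), default=0.0)
    rows = [
        (
            lam,
            len(expressed.get(lam, ())) / len(novel),
            (max_frac.get(lam, 0.0) / overall) if overall > 0 else 0.0,
        )
        for lam in lams
    ]
    return pd.DataFrame(
        rows, columns=["lam", "novel_fraction", "novel_max_cell_fraction"]
    )
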