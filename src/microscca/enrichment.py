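"""Pathway-term enrichment of selected microbial features.

Selected gene families (or species) are tested for over-representation
of annotation terms against a user-supplied background universe with a
two-sided Fisher's exact test per term, followed by Benjamini-Hochberg
FDR correction across terms.  The default reporting cut is q < 0.1.
Annotation maps are plain feature -> term files; no live database access.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "fisher_enrichment",
    "bh_fdr",
    "enrichment_table",
]


@dataclass
class AnnotationMap:
    """feature -> set of term ids, with optional term display names."""

    feature_terms: dict
    term_names: dict = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs, term_names=None):
        """Build from an iterable of (feature, term) pairs."""
        mapping: dict = {}
        for feat, term in pairs:
            mapping.setdefault(feat, set()).add(term)
        return cls(mapping, dict(term_names or {}))

    def terms(self):
        out = set()
        for s in self.feature_terms.values():
            out |= s
        return out

    def features_with(self, term):
        return {f for f, s in self.feature_terms.items() if term in s}


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's 2x2 table, odds ratio, p and BH q."""

    term: str
    selected_in_term: int
    selected_not_term: int
    background_in_term: int  # background-only (not selected) members of the term
    remainder: int
    odds_ratio: float
    p_value: float
    q_value: float

    @property
    def counts(self):
        return (
            self.selected_in_term,
            self.selected_not_term,
            self.background_in_term,
            self.remainder,
        )


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_i = min_{j: p_j >= p_i} p_j * m / rank_j`` -- monotone
    nondecreasing in p-rank and equivariant under input reordering.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def fisher_enrichment(
    selected, background, ann: AnnotationMap, sort: bool = True
) -> list[EnrichmentResult]:
    """Two-sided Fisher exact enrichment of every annotated term.

    The 2x2 table per term partitions the ``background`` universe into
    selected/unselected x in-term/not-in-term; counts always sum to the
    background size.  Terms with no background member are skipped.  BH
    correction runs across all terms tested.

    Returns results sorted by q-value (then p) unless ``sort=False``.
    """
    selected = set(selected)
    background = set(background)
    if not selected <= background:
        raise ValueError("selected features must be a subset of the background")
    if not selected:
        warnings.warn("empty selection: no enrichment computed", stacklevel=2)
        return []
    n_bg = len(background)
    n_sel = len(selected)
    rows = []
    for term in sorted(ann.terms(), key=str):
        members = ann.features_with(term) & background
        if not members:
            continue
        a = len(members & selected)
        b = n_sel - a
        c = len(members) - a
        d = n_bg - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((term, a, b, c, d, float(odds), float(p)))
    if not rows:
        return []
    qvals = bh_fdr([r[6] for r in rows])
    out = [
        EnrichmentResult(term, a, b, c, d, odds, p, float(q))
        for (term, a, b, c, d, odds, p), q in zip(rows, qvals)
    ]
    if sort:
        out.sort(key=lambda r: (r.q_value, r.p_value, str(r.term)))
    return out


def enrichment_table(results: list[EnrichmentResult], ann: AnnotationMap | None = None) -> pd.DataFrame:
    """Tabular view of enrichment results, sorted as given."""
    df = pd.DataFrame(
        [
            {
                "term": r.term,
                "name": (ann.term_names.get(r.term, "") if ann else ""),
                "selected_in_term": r.selected_in_term,
                "selected_not_term": r.selected_not_term,
                "background_in_term": r.background_in_term,
                "remainder": r.remainder,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ]
    )
    return df
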