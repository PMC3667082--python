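"""Background-harmonized two-sided Fisher exact testing of gene-list overlaps.

The overlap between two gene lists drawn from a shared background universe of
``N`` genes is summarized by the 2x2 membership table

    a = |A' ∩ B'|      b = |A' \\ B'|
    c = |B' \\ A'|      d = |background \\ (A' ∪ B')|

where ``A' = A ∩ background`` and ``B' = B ∩ background``.  Under the null,
``a`` is hypergeometric with mean (expected overlap) ``E = |A'|·|B'|/N``.
The two-sided p-value follows the minimum-likelihood (point-probability)
convention: it sums the probabilities of all outcomes ``k`` whose
hypergeometric probability does not exceed that of the observed overlap,
``p = Σ_{k : P(k) ≤ P(a)} P(k)``, so it is sensitive to both enrichment
(``a > E``) and depletion (``a < E``).  Probabilities are evaluated through
log-gamma, so backgrounds of tens of thousands of genes pose no overflow
problem, and the ``P(k) ≤ P(a)`` comparison carries a relative tolerance of
1e-7 to absorb floating-point ties.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import harmonize_universe
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "SignatureComparisonReport",
    "tsfet",
    "tsfet_counts",
    "compare_signatures",
    "batch_overlap_table",
    "results_to_frame",
]

#: relative tolerance used when comparing P(k) <= P(a); absorbs float ties
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class OverlapResult:
    """Outcome of one two-sided Fisher exact overlap test."""

    n_background: int
    n_a: int
    n_b: int
    overlap: int
    expected: float
    p_value: float
    direction: str  # 'enriched' | 'depleted' | 'none'
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def counts_2x2(self) -> tuple[int, int, int, int]:
        """(a, b, c, d): overlap, A-only, B-only, neither."""
        a = self.overlap
        b = self.n_a - a
        c = self.n_b - a
        d = self.n_background - self.n_a - self.n_b + a
        return a, b, c, d

    def to_dict(self) -> dict:
        return {
            "n_background": self.n_background,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "overlap": self.overlap,
            "expected": self.expected,
            "p_value": self.p_value,
            "direction": self.direction,
            "significant": self.significant,
            "alpha": self.alpha,
        }


def _two_sided_p(a: int, n_a: int, n_b: int, n: int) -> float:
    """Minimum-likelihood two-sided hypergeometric p-value via log-gamma."""
    lo = max(0, n_a + n_b - n)
    hi = min(n_a, n_b)
    if lo == hi:  # degenerate support: only one possible table
        return 1.0
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, n, n_a, n_b)
    log_cut = hypergeom.logpmf(a, n, n_a, n_b) + np.log1p(TIE_RTOL)
    p = float(np.exp(logpmf[logpmf <= log_cut]).sum())
    return min(p, 1.0)


def tsfet_counts(
    overlap: int,
    n_a: int,
    n_b: int,
    n_background: int,
    alpha: float = 0.05,
) -> OverlapResult:
    """Two-sided Fisher exact overlap test from the four summary counts.

    This is the count-level core of :func:`tsfet`; it is what reproduces a
    published overlap table from the printed list sizes alone.
    """
    if n_background <= 0:
        raise ValueError("background must be nonempty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_a > n_background or n_b > n_background:
        raise ValueError("list size exceeds background size")
    if not max(0, n_a + n_b - n_background) <= overlap <= min(n_a, n_b):
        raise ValueError(
            f"impossible overlap {overlap} for sizes ({n_a}, {n_b}) in background {n_background}"
        )
    expected = n_a * n_b / n_background
    p = _two_sided_p(overlap, n_a, n_b, n_background)
    if overlap > expected:
        direction = "enriched"
    elif overlap < expected:
        direction = "depleted"
    else:
        direction = "none"
    return OverlapResult(
        n_background=n_background,
        n_a=n_a,
        n_b=n_b,
        overlap=overlap,
        expected=expected,
        p_value=p,
        direction=direction,
        alpha=alpha,
    )


def tsfet(
    list_a: Iterable[str],
    list_b: Iterable[str],
    background: Iterable[str],
    alpha: float = 0.05,
) -> OverlapResult:
    """Two-sided Fisher exact test of the overlap of two gene lists.

    Both lists are first restricted to the background universe; genes outside
    it do not count toward the overlap or the list sizes.
    """
    bg = frozenset(background)
    if not bg:
        raise ValueError("background must be nonempty")
    a_set = frozenset(list_a) & bg
    b_set = frozenset(list_b) & bg
    return tsfet_counts(len(a_set & b_set), len(a_set), len(b_set), len(bg), alpha)


@dataclass(frozen=True)
class SignatureComparisonReport:
    """All four direction pairings of two signatures on a shared background."""

    name_a: str
    name_b: str
    n_background: int
    alpha: float
    results: dict[tuple[str, str], OverlapResult] = field(repr=False)

    def __getitem__(self, key: tuple[str, str]) -> OverlapResult:
        return self.results[key]

    def to_frame(self) -> pd.DataFrame:
        rows = {
            f"{self.name_a}^{sa}-{self.name_b}^{sb}": res.to_dict()
            for (sa, sb), res in self.results.items()
        }
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "pair"
        return frame


def compare_signatures(
    sig_a: GeneSignature, sig_b: GeneSignature, alpha: float = 0.05
) -> SignatureComparisonReport:
    """Run the overlap test for (up,up), (down,down), (up,down), (down,up)
    on the harmonized background of the two signature universes."""
    background = harmonize_universe(sig_a.universe, sig_b.universe)
    results = {
        (sa, sb): tsfet(sig_a.side(sa), sig_b.side(sb), background, alpha)
        for sa, sb in (("up", "up"), ("down", "down"), ("up", "down"), ("down", "up"))
    }
    return SignatureComparisonReport(
        name_a=sig_a.name,
        name_b=sig_b.name,
        n_background=len(background),
        alpha=alpha,
        results=results,
    )


def batch_overlap_table(
    signatures_a: Sequence[GeneSignature],
    signatures_b: Sequence[GeneSignature],
    alpha: float = 0.05,
    *,
    sides: Sequence[tuple[str, str]] = (("up", "up"), ("down", "down"), ("up", "down"), ("down", "up")),
) -> pd.DataFrame:
    """Row-major grid of overlap tests between two lists of signatures.

    Each cell harmonizes the background of its own signature pair, mirroring
    the layout of published subtype-by-signature overlap grids.  Returns a
    long-format frame with one row per (pair of signatures, direction pair).
    """
    if not signatures_a or not signatures_b:
        raise ValueError("signature lists must be nonempty")
    records = []
    for sig_a in signatures_a:
        for sig_b in signatures_b:
            background = harmonize_universe(sig_a.universe, sig_b.universe)
            for sa, sb in sides:
                res = tsfet(sig_a.side(sa), sig_b.side(sb), background, alpha)
                records.append(
                    {"sig_a": sig_a.name, "sig_b": sig_b.name, "side_a": sa, "side_b": sb}
                    | res.to_dict()
                )
    return pd.DataFrame.from_records(records)


def results_to_frame(results: dict[str, OverlapResult]) -> pd.DataFrame:
    """Flatten a {label: OverlapResult} mapping into a report frame."""
    frame = pd.DataFrame.from_dict(
        {label: res.to_dict() for label, res in results.items()}, orient="index"
    )
    frame.index.name = "pair"
    return frame


def write_overlap_report(frame: pd.DataFrame, path: str | Path, *, digits: int = 2) -> None:
    """TSV export with the display-rounded expected overlap alongside the
    full-precision value."""
    out = frame.copy()
    if "expected" in out.columns:
        out.insert(
            out.columns.get_loc("expected") + 1,
            "expected_rounded",
            out["expected"].round(digits),
        )
    out.to_csv(path, sep="\t")
    Path(str(path) + ".json").write_text(json.dumps(out.reset_index().to_dict("records"), indent=1))
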