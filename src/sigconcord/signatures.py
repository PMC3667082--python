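"""Fold-change gene signatures.

A signature is a named pair of disjoint up/down-regulated gene sets together
with the universe it was derived from and the log2 threshold used.  Three
derivation rules are provided, matching the three study designs the pipeline
supports:

* group vs. reference (e.g. tumor vs. normal): difference of group means,
* subtype vs. the mean of all other subtypes,
* paired single samples (e.g. marker-sorted positive vs. negative fractions),
  with a multi-pair consensus rule (a gene must recur in at least
  ``min_support`` pairs).

"Fold change" is always the difference of log2 means, i.e. the log2 of the
ratio of geometric means, and the threshold is inclusive: a gene is called
when \\|log2 FC\\| >= tau.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_signature_file, write_signature_file

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "derive_group_signature",
    "derive_subtype_vs_rest_signature",
    "derive_paired_signature",
    "intersect_signatures",
    "per_sample_log2fc",
]


@dataclass(frozen=True)
class GeneSignature:
    """Named pair of disjoint up/down gene sets plus their derivation universe.

    ``threshold_log2`` (tau) is the inclusive |log2 fold change| cutoff the
    signature was derived at; the pipeline presets are 1.0 (two-fold) and the
    relaxed 0.5.
    """

    name: str
    up: frozenset[str]
    down: frozenset[str]
    universe: frozenset[str]
    threshold_log2: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        object.__setattr__(self, "universe", frozenset(self.universe))
        if self.threshold_log2 <= 0:
            raise ValueError("threshold_log2 must be positive")
        if self.up & self.down:
            raise ValueError(
                f"signature {self.name!r}: up and down sets overlap "
                f"({sorted(self.up & self.down)[:5]}...)"
            )
        stray = (self.up | self.down) - self.universe
        if stray:
            raise ValueError(
                f"signature {self.name!r}: {len(stray)} signature genes outside the universe"
            )

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    def side(self, which: str) -> frozenset[str]:
        if which not in ("up", "down"):
            raise ValueError(f"side must be 'up' or 'down', got {which!r}")
        return self.up if which == "up" else self.down

    def restrict(self, background: Iterable[str]) -> "GeneSignature":
        """Intersect all three gene sets with ``background``."""
        bg = frozenset(background)
        return replace(
            self, up=self.up & bg, down=self.down & bg, universe=self.universe & bg
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "up": sorted(self.up),
            "down": sorted(self.down),
            "universe_size": len(self.universe),
            "universe": sorted(self.universe),
            "threshold_log2": self.threshold_log2,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GeneSignature":
        return cls(
            name=payload["name"],
            up=frozenset(payload["up"]),
            down=frozenset(payload["down"]),
            universe=frozenset(payload["universe"]),
            threshold_log2=float(payload.get("threshold_log2", 1.0)),
        )

    def save(self, path: str | Path) -> None:
        """Plain-text export with #up/#down sections (universe not stored)."""
        write_signature_file(path, self.up, self.down)

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(
        cls,
        path: str | Path,
        universe: Iterable[str] | None = None,
        *,
        name: str | None = None,
        threshold_log2: float = 1.0,
    ) -> "GeneSignature":
        """Load a #up/#down text file.  If no universe is given, the union of
        the two sets is used (adequate only for set arithmetic, not for
        overlap testing)."""
        up, down = read_signature_file(path)
        if universe is None:
            universe = set(up) | set(down)
        return cls(
            name=name or Path(path).stem,
            up=frozenset(up),
            down=frozenset(down),
            universe=frozenset(universe),
            threshold_log2=threshold_log2,
        )


def _check_samples(expr: pd.DataFrame, samples: Sequence[str], what: str) -> list[str]:
    samples = list(samples)
    if not samples:
        raise ValueError(f"{what} sample set is empty")
    missing = [s for s in samples if s not in expr.columns]
    if missing:
        raise ValueError(f"{what} samples not in matrix: {missing[:5]}")
    return samples


def derive_group_signature(
    expr: pd.DataFrame,
    group_samples: Sequence[str],
    reference_samples: Sequence[str],
    tau: float = 1.0,
    *,
    name: str = "signature",
) -> GeneSignature:
    """Signature of ``group`` vs. ``reference`` by mean log2 fold change.

    A gene is up if mean(group) - mean(reference) >= tau and down if it is
    <= -tau (inclusive boundaries).  The universe is the full gene set of
    ``expr``.
    """
    group = _check_samples(expr, group_samples, "group")
    reference = _check_samples(expr, reference_samples, "reference")
    overlap = set(group) & set(reference)
    if overlap:
        raise ValueError(f"group and reference overlap: {sorted(overlap)[:5]}")
    if tau <= 0:
        raise ValueError("tau must be positive")
    diff = expr[group].mean(axis=1) - expr[reference].mean(axis=1)
    return GeneSignature(
        name=name,
        up=frozenset(diff.index[diff >= tau]),
        down=frozenset(diff.index[diff <= -tau]),
        universe=frozenset(expr.index),
        threshold_log2=tau,
    )


def derive_subtype_vs_rest_signature(
    expr: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    subtype: str,
    tau: float = 1.0,
) -> GeneSignature:
    """Signature of one subtype against the pooled mean of all other subtypes."""
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    if labels.nunique() < 2:
        raise ValueError("need at least two distinct subtype labels")
    members = labels.index[labels == subtype].tolist()
    rest = labels.index[labels != subtype].tolist()
    if not members:
        raise ValueError(f"subtype {subtype!r} absent from labels")
    return derive_group_signature(expr, members, rest, tau, name=f"{subtype}_vs_rest")


def derive_paired_signature(
    expr: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    tau: float = 1.0,
    min_support: int = 2,
    *,
    name: str = "consensus",
) -> tuple[dict[str, GeneSignature], GeneSignature]:
    """Per-pair signatures from single-sample differences, plus a consensus.

    Each pair (positive, negative) yields a signature from the difference
    ``expr[pos] - expr[neg]`` thresholded at +-tau.  The consensus contains
    genes called up (respectively down) in at least ``min_support`` pairs;
    a gene reaching support in both directions is removed from both and
    logged.
    """
    if not pairs:
        raise ValueError("no pairs given")
    for pos, neg in pairs:
        if pos == neg:
            raise ValueError(f"pair with identical sample ids: {pos!r}")
        _check_samples(expr, [pos, neg], "pair")
    if not 1 <= min_support <= len(pairs):
        raise ValueError(f"min_support must be in 1..{len(pairs)}")
    universe = frozenset(expr.index)
    per_pair: dict[str, GeneSignature] = {}
    up_support = pd.Series(0, index=expr.index)
    down_support = pd.Series(0, index=expr.index)
    for pos, neg in pairs:
        diff = expr[pos] - expr[neg]
        up = diff >= tau
        down = diff <= -tau
        pair_name = f"{pos}_vs_{neg}"
        per_pair[pair_name] = GeneSignature(
            name=pair_name,
            up=frozenset(diff.index[up]),
            down=frozenset(diff.index[down]),
            universe=universe,
            threshold_log2=tau,
        )
        up_support += up.astype(int)
        down_support += down.astype(int)
    cons_up = set(expr.index[up_support >= min_support])
    cons_down = set(expr.index[down_support >= min_support])
    conflict = cons_up & cons_down
    if conflict:
        logger.warning(
            "paired consensus %r: %d genes reached support in both directions; "
            "removed from both sets",
            name,
            len(conflict),
        )
        cons_up -= conflict
        cons_down -= conflict
    consensus = GeneSignature(
        name=name,
        up=frozenset(cons_up),
        down=frozenset(cons_down),
        universe=universe,
        threshold_log2=tau,
    )
    return per_pair, consensus


def intersect_signatures(signatures: Sequence[GeneSignature], *, name: str) -> GeneSignature:
    """Core signature shared by several signatures: intersection of the up
    sets, intersection of the down sets, intersection of the universes.

    This is how a robust core signature is distilled from the responses to
    several independent perturbations (e.g. five different EMT inducers).
    """
    if not signatures:
        raise ValueError("no signatures to intersect")
    up = frozenset.intersection(*(s.up for s in signatures))
    down = frozenset.intersection(*(s.down for s in signatures))
    universe = frozenset.intersection(*(s.universe for s in signatures))
    tau = max(s.threshold_log2 for s in signatures)
    return GeneSignature(name=name, up=up & universe, down=down & universe,
                         universe=universe, threshold_log2=tau)


def per_sample_log2fc(expr: pd.DataFrame, reference_samples: Sequence[str]) -> pd.DataFrame:
    """Per-sample log2 fold-change matrix vs. the reference-group mean.

    ``fc[g, s] = expr[g, s] - mean(expr[g, reference])`` for every sample
    column of ``expr`` (reference columns included; their FC is their
    deviation from the reference mean).
    """
    reference = _check_samples(expr, reference_samples, "reference")
    ref_mean = expr[reference].mean(axis=1)
    return expr.sub(ref_mean, axis=0)
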