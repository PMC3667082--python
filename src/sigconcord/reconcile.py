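"""Three-way discordance analysis between signatures.

When a subtype signature (B) resembles two mutually opposed signatures (A
and C) at once, its disagreements with each can be explained by its
agreement with the other.  The analysis builds the discordant sets between A
and B (genes down in A but up in B, and vice versa) and asks whether they
coincide with the matching side of C — and symmetrically for the C/B
discordant sets against A.  All four tests run on the triple-harmonized
background: genes measured in all three datasets.

Because the discordant sets shrink quickly, signatures for this analysis are
customarily re-derived at a relaxed threshold (0.5 instead of 1.0 on the
log2 scale) so the three-way intersections are populated.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from .io import harmonize_universe
from .overlap import OverlapResult, tsfet
from .signatures import GeneSignature, derive_group_signature

logger = logging.getLogger(__name__)

__all__ = [
    "DiscordantSets",
    "discordant_sets",
    "reconcile",
    "three_way_report",
    "three_way_pipeline",
]


@dataclass(frozen=True)
class DiscordantSets:
    """Genes regulated in opposite directions by two signatures."""

    name_a: str
    name_b: str
    a_down_b_up: frozenset[str]
    a_up_b_down: frozenset[str]
    background: frozenset[str]


def discordant_sets(
    sig_a: GeneSignature, sig_b: GeneSignature, background: Iterable[str]
) -> DiscordantSets:
    """Build both discordant gene sets of two signatures on a background."""
    bg = frozenset(background)
    if not bg:
        raise ValueError("background must be nonempty")
    return DiscordantSets(
        name_a=sig_a.name,
        name_b=sig_b.name,
        a_down_b_up=sig_a.down & sig_b.up & bg,
        a_up_b_down=sig_a.up & sig_b.down & bg,
        background=bg,
    )


def reconcile(
    discordant_set: Iterable[str],
    third_sig_side: Iterable[str],
    background: Iterable[str],
    alpha: float = 0.05,
) -> OverlapResult:
    """Overlap test of a discordant set against one side of a third signature."""
    return tsfet(discordant_set, third_sig_side, background, alpha)


def three_way_report(
    sig_a: GeneSignature,
    sig_b: GeneSignature,
    sig_c: GeneSignature,
    alpha: float = 0.05,
) -> dict[str, OverlapResult | None]:
    """The four reconciliation tests between a subtype signature B and two
    opposed signatures A and C on the triple-harmonized background.

    Tests (labels use the signature names):
      * (A.down ∩ B.up)   vs C.up
      * (A.up   ∩ B.down) vs C.down
      * (C.down ∩ B.up)   vs A.up
      * (C.up   ∩ B.down) vs A.down

    A test whose discordant set is empty is recorded as ``None`` with a
    logged notice.
    """
    background = harmonize_universe(sig_a.universe, sig_b.universe, sig_c.universe)
    ab = discordant_sets(sig_a, sig_b, background)
    cb = discordant_sets(sig_c, sig_b, background)
    a, b, c = sig_a.name, sig_b.name, sig_c.name
    plan = [
        ("a_down_b_up_vs_c_up", f"{a}^down-{b}^up vs {c}^up", ab.a_down_b_up, sig_c.up),
        ("a_up_b_down_vs_c_down", f"{a}^up-{b}^down vs {c}^down", ab.a_up_b_down, sig_c.down),
        ("c_down_b_up_vs_a_up", f"{c}^down-{b}^up vs {a}^up", cb.a_down_b_up, sig_a.up),
        ("c_up_b_down_vs_a_down", f"{c}^up-{b}^down vs {a}^down", cb.a_up_b_down, sig_a.down),
    ]
    report: dict[str, OverlapResult | None] = {}
    for key, label, discordant, third_side in plan:
        if not discordant:
            logger.info("three_way_report: %s skipped (empty discordant set)", label)
            report[key] = None
        else:
            report[key] = reconcile(discordant, third_side, background, alpha)
    return report


def three_way_pipeline(
    expr: pd.DataFrame,
    subtype_samples: Sequence[str],
    reference_samples: Sequence[str],
    sig_a: GeneSignature,
    sig_c: GeneSignature,
    *,
    subtype_name: str = "subtype",
    tau: float = 0.5,
    alpha: float = 0.05,
) -> dict[str, OverlapResult | None]:
    """Re-derive the subtype signature at a relaxed threshold and run the
    full three-way analysis against two externally derived signatures.

    ``sig_a`` and ``sig_c`` are expected to have been derived at the same
    relaxed ``tau`` from their own datasets; the background is the
    intersection of all three universes.
    """
    sig_b = derive_group_signature(
        expr, subtype_samples, reference_samples, tau, name=subtype_name
    )
    return three_way_report(sig_a, sig_b, sig_c, alpha)
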