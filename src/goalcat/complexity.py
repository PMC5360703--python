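"""Characteristic-parameter counts and the structure-comparison inequalities.

Complexity is measured by counting conditional-probability-table cells of the
blocks that *differ* between two competing structures (their characteristic
parameters); blocks shared by both structures — feature→observation mappings,
and in the later comparisons the high-order machinery — are excluded. Counts
are whole cell counts, not cells minus normalization constraints: that is the
convention under which the closed forms below match brute-force enumeration on
the constructed models.

Three pairwise comparisons are defined:

flat vs latent
    P1 = n_f^F · n_a · n_g          (goal given all features and action)
    P2 = n_f^F · n_L1 + n_L1 · n_a · n_g
    The latent model is cheaper iff n_L1 < n_f^F·n_a·n_g / (n_f^F + n_a·n_g).

latent vs hierarchical
    P2 = n_f1^F1 · n_f2^F2 · n_L1   (one latent generates both feature subsets)
    P3 = n_f2^F2 · n_L1 · n_L2 + n_f1^F1 · n_L1
    The hierarchy is cheaper iff n_L2 < n_f1^F1 · (n_f2^F2 − 1) / n_f2^F2
    (the shared n_L1 factor cancels from both sides).

hierarchical vs contextual
    P3 = n_f1^F1 · n_L1 · n_c · n_g · n_a   (context folded into the latent)
    P4 = n_f1^F1 · n_L1 + n_L1 · n_c · n_g · n_a
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from . import model_zoo
from .gm_core import count_block_cells
from .model_zoo import StructureConfig

__all__ = [
    "ComparisonResult",
    "CHARACTERISTIC_BLOCKS",
    "characteristic_cell_count",
    "compare_flat_vs_latent",
    "compare_latent_vs_hierarchical",
    "compare_hierarchical_vs_contextual",
    "COMPARISONS",
]

#: blocks whose cells constitute each structure's characteristic parameters,
#: keyed by the builder name in :mod:`goalcat.model_zoo`
CHARACTERISTIC_BLOCKS = {
    "m1": ("goal",),
    "m2": ("features", "goal"),
    "m2_split": ("features",),
    "m3": ("hier", "features1"),
    "m3_context_folded": ("features_goal",),
    "m4": ("features1", "goal"),
}


@dataclass(frozen=True)
class ComparisonResult:
    """Cell counts of two rival structures, the decision threshold, the winner."""

    comparison: str
    count_a: int
    count_b: int
    threshold: Optional[float]
    threshold_on: Optional[str]
    preferred: str  # "a" | "b" | "tie"

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "count_a": self.count_a,
            "count_b": self.count_b,
            "threshold": self.threshold,
            "threshold_on": self.threshold_on,
            "preferred": self.preferred,
        }


def _prefer(count_a: int, count_b: int) -> str:
    if count_a < count_b:
        return "a"
    if count_b < count_a:
        return "b"
    return "tie"


def characteristic_cell_count(structure: str, cfg: StructureConfig) -> int:
    """Brute-force characteristic count: build the model, count its blocks' cells."""
    model = model_zoo.BUILDERS[structure](cfg)
    indices = [model.block_index(n) for n in CHARACTERISTIC_BLOCKS[structure]]
    return count_block_cells(model, indices)


def compare_flat_vs_latent(cfg: StructureConfig) -> ComparisonResult:
    """Model one (a) against Model two (b) on the flat feature set."""
    nfF = cfg.n_f**cfg.F
    count_a = nfF * cfg.n_a * cfg.n_g
    count_b = nfF * cfg.n_L1 + cfg.n_L1 * cfg.n_a * cfg.n_g
    threshold = Fraction(nfF * cfg.n_a * cfg.n_g, nfF + cfg.n_a * cfg.n_g)
    return ComparisonResult(
        "flat_vs_latent", count_a, count_b, float(threshold), "n_L1",
        _prefer(count_a, count_b),
    )


def compare_latent_vs_hierarchical(cfg: StructureConfig) -> ComparisonResult:
    """Model two over both feature subsets (a) against Model three (b)."""
    nf1F1 = cfg.n_f1**cfg.F1
    nf2F2 = cfg.n_f2**cfg.F2
    count_a = nf1F1 * nf2F2 * cfg.n_L1
    count_b = nf2F2 * cfg.n_L1 * cfg.n_L2 + nf1F1 * cfg.n_L1
    threshold = Fraction(nf1F1 * (nf2F2 - 1), nf2F2)
    return ComparisonResult(
        "latent_vs_hierarchical", count_a, count_b, float(threshold), "n_L2",
        _prefer(count_a, count_b),
    )


def compare_hierarchical_vs_contextual(cfg: StructureConfig) -> ComparisonResult:
    """Context folded into the latent (a) against an explicit context variable (b).

    ``cfg.n_L1`` is the content-only latent cardinality; the folded rival's
    latent carries ``n_L1 * n_c`` states. No closed-form threshold accompanies
    this comparison; the counts themselves decide.
    """
    nf1F1 = cfg.n_f1**cfg.F1
    count_a = nf1F1 * cfg.n_L1 * cfg.n_c * cfg.n_g * cfg.n_a
    count_b = nf1F1 * cfg.n_L1 + cfg.n_L1 * cfg.n_c * cfg.n_g * cfg.n_a
    return ComparisonResult(
        "hierarchical_vs_contextual", count_a, count_b, None, None,
        _prefer(count_a, count_b),
    )


COMPARISONS = {
    "flat-latent": (compare_flat_vs_latent, ("m1", "m2")),
    "latent-hier": (compare_latent_vs_hierarchical, ("m2_split", "m3")),
    "hier-context": (compare_hierarchical_vs_contextual, ("m3_context_folded", "m4")),
}
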