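"""Gene-dependency classification over a 2x2 genotype-by-diet design.

Four pairwise contrasts span the design (WT = wild type, OE = miR-21
overexpression, NCD/HCD = normal/high-cholesterol diet):

    A: WT-HCD  vs WT-NCD      (diet effect in wild type)
    B: OE-NCD  vs WT-NCD      (genotype effect on normal diet)
    C: OE-HCD  vs WT-HCD      (genotype effect on high-cholesterol diet)
    D: OE-HCD  vs OE-NCD      (diet effect in the overexpressor)

Genes are classified by set logic over per-contrast significance calls:

- ``diet_dependent``: significant in the same direction in A and D, and not
  significant in B or C (the diet moves the gene regardless of genotype).
- ``mir21_dependent``: significant in the same direction in B and C (the
  transgene moves the gene regardless of diet).
- ``divergent``: significant in A and C in opposite directions (the
  transgene's response to diet opposes the physiologic one).
- ``mir21_hcd_dependent``: significant in C and D, not in B, and not
  classified diet-dependent (the gene needs both transgene and diet).

Overlaps are resolved by a fixed precedence (divergent > mir21_dependent >
diet_dependent > mir21_hcd_dependent), configurable via ClassRules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de_io import DETable

LABELS = ("divergent", "mir21_dependent", "diet_dependent", "mir21_hcd_dependent")


@dataclass
class ClassRules:
    require_same_direction: bool = True
    precedence: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        if set(self.precedence) != set(LABELS):
            raise ValueError(f"precedence must permute {LABELS}")


@dataclass
class ContrastQuad:
    """The four factorial contrasts, each a DETable with significance calls."""

    A: DETable
    B: DETable
    C: DETable
    D: DETable

    def __post_init__(self) -> None:
        for name in "ABCD":
            t = getattr(self, name)
            if "significant" not in t.df.columns:
                raise ValueError(f"contrast {name} lacks significance calls")

    def universe(self) -> list[str]:
        ids: set[str] = set()
        for name in "ABCD":
            ids.update(getattr(self, name).df["feature_id"])
        return sorted(ids)


def _calls(table: DETable, universe: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(significant, signed direction) aligned to the universe.

    Genes absent from a contrast are treated as not significant there.
    """
    df = table.df.set_index("feature_id")
    sig = np.zeros(len(universe), dtype=bool)
    sgn = np.zeros(len(universe), dtype=int)
    idx = {g: i for i, g in enumerate(universe)}
    present = df.index.intersection(universe)
    pos = np.array([idx[g] for g in present], dtype=int)
    if len(pos):
        sig[pos] = df.loc[present, "significant"].to_numpy(dtype=bool)
        d = df.loc[present, "direction"].to_numpy()
        sgn[pos] = np.where(d == "up", 1, np.where(d == "down", -1, 0))
    return sig, sgn


def classify_genes(quad: ContrastQuad, rules: ClassRules | None = None) -> pd.DataFrame:
    """Assign each gene in the quad's universe a dependency label.

    Returns a frame with columns ``gene_id, label, direction`` where label is
    one of the four classes or ``none`` and direction is ``up``/``down``/
    ``mixed``/``none``.  Deterministic and invariant to row order.
    """
    rules = rules or ClassRules()
    universe = quad.universe()
    sigA, dirA = _calls(quad.A, universe)
    sigB, dirB = _calls(quad.B, universe)
    sigC, dirC = _calls(quad.C, universe)
    sigD, dirD = _calls(quad.D, universe)

    same_AD = dirA == dirD
    same_BC = dirB == dirC
    if not rules.require_same_direction:
        same_AD = np.ones_like(same_AD)

    diet = sigA & sigD & same_AD & ~sigB & ~sigC
    mir21 = sigB & sigC & same_BC
    divergent = sigA & sigC & (dirA * dirC == -1)
    mir21_hcd = sigC & sigD & ~sigB & ~diet

    masks = {
        "diet_dependent": diet,
        "mir21_dependent": mir21,
        "divergent": divergent,
        "mir21_hcd_dependent": mir21_hcd,
    }
    label = np.full(len(universe), "none", dtype=object)
    for lab in reversed(rules.precedence):  # highest precedence applied last
        label[masks[lab]] = lab

    direction = np.full(len(universe), "none", dtype=object)

    def _dir(mask: np.ndarray, d1: np.ndarray, d2: np.ndarray) -> None:
        agree = d1 == d2
        direction[mask & agree & (d1 > 0)] = "up"
        direction[mask & agree & (d1 < 0)] = "down"
        direction[mask & ~agree] = "mixed"

    _dir(label == "diet_dependent", dirA, dirD)
    _dir(label == "mir21_dependent", dirB, dirC)
    _dir(label == "mir21_hcd_dependent", dirC, dirD)
    direction[label == "divergent"] = "mixed"

    return pd.DataFrame({"gene_id": universe, "label": label, "direction": direction})


def class_counts(classes: pd.DataFrame) -> pd.DataFrame:
    """Per-label up/down/mixed/total tallies over a classify_genes frame."""
    out = []
    for lab in LABELS:
        sub = classes[classes["label"] == lab]
        out.append(
            {
                "label": lab,
                "up": int((sub["direction"] == "up").sum()),
                "down": int((sub["direction"] == "down").sum()),
                "mixed": int((sub["direction"] == "mixed").sum()),
                "total": int(len(sub)),
            }
        )
    return pd.DataFrame(out)
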