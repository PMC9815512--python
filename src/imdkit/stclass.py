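"""ROI classification by CD8 infiltration and class-vs-class expression.

Each spatial-transcriptomics ROI carries a CD8+ cell count and a nuclei
count; their ratio is the positive index.  ROIs are classified CD8-high
(index > 20 %), CD8-low (index < 5 %) or intermediate (boundaries fall in
the intermediate class: the outer-class inequalities are strict).
Expression is normalised per ROI to the geometric mean of a user-chosen
target gene group, then classes are compared gene-by-gene with unpaired
two-tailed t tests on log2 values, BH-adjusted, and the resulting gene
list is fed to the shared hypergeometric over-representation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust, hypergeom_ora
from .geometry import ValidationError

__all__ = [
    "positive_index",
    "classify_roi",
    "geomean_normalize",
    "class_de",
    "STROIData",
    "STClassificationModel",
    "STClassificationResults",
]

HIGH_THRESHOLD = 0.20
LOW_THRESHOLD = 0.05
CLASSES = ("high", "intermediate", "low")


def positive_index(cd8_count, nuclei_count):
    """CD8+ cells / nuclei — the infiltration index of an ROI."""
    cd8 = np.asarray(cd8_count, dtype=float)
    nuc = np.asarray(nuclei_count, dtype=float)
    if (nuc <= 0).any():
        raise ValidationError("nuclei count must be positive")
    if (cd8 > nuc).any():
        raise ValidationError("CD8 count cannot exceed nuclei count")
    out = cd8 / nuc
    return float(out) if out.ndim == 0 else out


def classify_roi(index):
    """Three-class CD8 infiltration label from the positive index.

    high if index > 0.20, low if index < 0.05, intermediate otherwise —
    the boundary values 0.05 and 0.20 classify as intermediate.
    """
    idx = np.asarray(index, dtype=float)
    if ((idx < 0) | (idx > 1)).any():
        raise ValidationError("positive index must lie in [0, 1]")
    out = np.where(idx > HIGH_THRESHOLD, "high", np.where(idx < LOW_THRESHOLD, "low", "intermediate"))
    return str(out) if out.ndim == 0 else pd.Series(out, name="cd8_class")


def geomean_normalize(
    expression: pd.DataFrame,
    target_group: Sequence[str],
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Divide each ROI's expression by its target-group geometric mean.

    ``expression`` is ROI x gene.  After normalisation the geometric mean of
    the target-group genes equals 1 in every ROI, which makes the operation
    idempotent.  Target-group values must be positive (after pseudocount).
    """
    targets = [g for g in target_group if g in expression.columns]
    if not targets:
        raise ValidationError("empty target group (no overlap with expression genes)")
    vals = expression.astype(float) + pseudocount
    tg = vals[targets]
    if (tg <= 0).any().any():
        raise ValidationError("target-group expression must be positive")
    gm = np.exp(np.log(tg).mean(axis=1))
    return vals.div(gm, axis=0)


def class_de(
    rois: "STROIData",
    class_a: str,
    class_b: str,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential expression between two CD8 classes.

    Two-tailed unpaired t test on log2 normalised expression, BH-adjusted
    across genes.  Returns ``gene, mean_log2fc, t_statistic, p_value,
    p_adjusted, significant`` with fold change oriented class_a vs class_b.
    """
    for c in (class_a, class_b):
        if c not in CLASSES:
            raise ValidationError(f"unknown class {c!r}")
    expr = rois.normalized_expression()
    ga = expr[rois.meta["cd8_class"] == class_a]
    gb = expr[rois.meta["cd8_class"] == class_b]
    if len(ga) < 2 or len(gb) < 2:
        raise ValidationError("each class needs >= 2 ROIs for a t test")
    la, lb = np.log2(ga.to_numpy(float)), np.log2(gb.to_numpy(float))
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_ind(la, lb, axis=0, equal_var=equal_var)
    p = np.where(np.isfinite(p), p, 1.0)
    res = pd.DataFrame(
        {
            "gene": expr.columns,
            "mean_log2fc": la.mean(axis=0) - lb.mean(axis=0),
            "t_statistic": t,
            "p_value": p,
        }
    )
    res["p_adjusted"] = bh_adjust(res["p_value"])
    res["significant"] = res["p_adjusted"] < alpha
    return res


@dataclass
class STROIData:
    """Per-ROI CD8 counts plus a gene-expression matrix.

    ``meta`` columns: roi_id, cd8_count, nuclei_count, positive_index,
    cd8_class.  ``expression`` is raw counts/intensities, ROI x gene,
    indexed like ``meta`` by roi_id.
    """

    meta: pd.DataFrame
    expression: pd.DataFrame = field(repr=False)
    target_group: list[str] | None = None

    @classmethod
    def from_counts(
        cls,
        roi_ids: Sequence,
        cd8_counts: Sequence[int],
        nuclei_counts: Sequence[int],
        expression: pd.DataFrame,
        target_group: Sequence[str] | None = None,
    ) -> "STROIData":
        idx = positive_index(cd8_counts, nuclei_counts)
        meta = pd.DataFrame(
            {
                "roi_id": list(roi_ids),
                "cd8_count": list(cd8_counts),
                "nuclei_count": list(nuclei_counts),
                "positive_index": np.atleast_1d(idx),
            }
        ).set_index("roi_id", drop=False)
        meta["cd8_class"] = classify_roi(meta["positive_index"]).to_numpy()
        expr = expression.copy()
        expr.index = meta.index
        return cls(meta, expr, list(target_group) if target_group else None)

    @property
    def class_counts(self) -> dict[str, int]:
        vc = self.meta["cd8_class"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASSES}

    def normalized_expression(self) -> pd.DataFrame:
        if not self.target_group:
            raise ValidationError("target_group is required for normalisation")
        return geomean_normalize(self.expression, self.target_group)


@dataclass
class STClassificationResults:
    """Classification summary and class-vs-class DE / enrichment."""

    data: STROIData
    de: dict[tuple[str, str], pd.DataFrame]
    model: "STClassificationModel" = field(repr=False, default=None)

    @property
    def class_counts(self) -> dict[str, int]:
        return self.data.class_counts

    def enrichment(
        self, sets: Mapping[str, Sequence[str]], contrast: tuple[str, str] = ("high", "low")
    ) -> pd.DataFrame:
        de = self.de[contrast]
        sig = sorted(de.loc[de["significant"], "gene"])
        return hypergeom_ora(sig, list(de["gene"]), sets)

    def summary(self) -> str:
        cc = self.class_counts
        lines = [
            "CD8-infiltration ROI classification",
            f"ROIs: {len(self.data.meta)}  "
            f"high: {cc['high']}  intermediate: {cc['intermediate']}  low: {cc['low']}",
        ]
        for (a, b), de in self.de.items():
            nsig = int(de["significant"].sum())
            lines.append(f"DE {a} vs {b}: {nsig} genes at BH < 0.05 (of {len(de)})")
        return "\n".join(lines)


class STClassificationModel:
    """CD8-classification + differential-expression model over ST ROIs.

    ``contrasts`` lists the class pairs to test (default high-vs-low and
    high-vs-intermediate when the data supports them).
    """

    def __init__(
        self,
        data: STROIData,
        contrasts: Sequence[tuple[str, str]] | None = None,
        equal_var: bool = True,
        alpha: float = 0.05,
    ) -> None:
        self.data = data
        self.contrasts = list(contrasts) if contrasts else None
        self.equal_var = equal_var
        self.alpha = alpha

    def fit(self) -> STClassificationResults:
        cc = self.data.class_counts
        contrasts = self.contrasts
        if contrasts is None:
            contrasts = [
                (a, b)
                for a, b in [("high", "low"), ("high", "intermediate")]
                if cc[a] >= 2 and cc[b] >= 2
            ]
        de = {
            (a, b): class_de(self.data, a, b, self.equal_var, self.alpha)
            for a, b in contrasts
        }
        return STClassificationResults(data=self.data, de=de, model=self)
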