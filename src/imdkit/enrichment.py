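"""Over-representation analysis shared by the metabolomics and ST stages.

A pathway here is nothing more than a named feature set supplied by the
user (e.g. read from a GMT file).  Enrichment of a significant-feature list
against each set is the one-sided hypergeometric upper tail, adjusted
across sets with Benjamini–Hochberg.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "hypergeom_ora"]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaN-safe, order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def hypergeom_ora(
    significant: Sequence[str],
    universe: Sequence[str],
    sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``significant`` in each set.

    Each set is intersected with the universe before testing; the p-value
    for a set of size K with overlap k is ``P(X >= k)`` for
    ``X ~ Hypergeom(M=len(universe), K, n=len(significant))``.  Results are
    BH-adjusted across sets and ranked by adjusted then raw p.

    Returns a DataFrame with columns
    ``set, set_size, overlap, p_value, p_adjusted``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sig = set(significant)
    if not sig <= uni:
        raise ValueError("significant features must be a subset of the universe")
    M, n = len(uni), len(sig)
    rows = []
    for name, members in sets.items():
        mem = set(members) & uni
        k = len(mem & sig)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(hypergeom.sf(k - 1, M, len(mem), n)) if mem else 1.0
        rows.append({"set": name, "set_size": len(mem), "overlap": k, "p_value": min(p, 1.0)})
    res = pd.DataFrame(rows)
    if res.empty:
        res["p_adjusted"] = []
        return res
    res["p_adjusted"] = bh_adjust(res["p_value"])
    res = res.sort_values(["p_adjusted", "p_value", "set"], kind="mergesort")
    return res.reset_index(drop=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Read feature sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "imdkit") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
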