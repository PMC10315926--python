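"""Functional-category enrichment by one-sided Fisher's exact test.

For a DEP set of size n drawn from a background universe of N quantified
proteins, of which K carry a given annotation term and k of the DEPs do, the
over-representation p-value is the upper hypergeometric tail
P(X >= k | N, K, n) and the enrichment factor is EF = (k/n) / (K/N).  A term
passes at the study thresholds when p < 0.05 and EF > 1.5.  Up- and
downregulated DEP sets are tested independently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping
import warnings

import numpy as np
import pandas as pd
from scipy import stats


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Term -> protein set from a two-column (protein, term) TSV or GMT file.

    GMT lines are ``term <tab> description <tab> protein...``; the two-column
    dialect is detected by its header naming both columns.
    """
    path = Path(path)
    first = path.open().readline().rstrip("\n").split("\t")
    terms: dict[str, set[str]] = {}
    if {"protein", "term"} <= set(c.strip().lower() for c in first):
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.strip().lower() for c in df.columns]
        for row in df.itertuples(index=False):
            terms.setdefault(str(row.term), set()).add(str(row.protein))
    else:  # GMT
        for line in path.read_text().splitlines():
            parts = line.rstrip().split("\t")
            if len(parts) >= 3:
                terms.setdefault(parts[0], set()).update(parts[2:])
    return terms


def fisher_enrichment(
    dep_set: Iterable[str],
    annotation: Mapping[str, set[str]],
    background: Iterable[str],
    alpha: float = 0.05,
    min_ef: float = 1.5,
    bh: bool = False,
) -> pd.DataFrame:
    """One-sided over-representation test of every term in a DEP set.

    Returns rows (term, k, n, K, N, p_value, enrichment_factor, passes)
    sorted by p-value then term.  Terms absent from the background (K = 0)
    are skipped with a warning; a DEP protein outside the background is an
    error.  ``bh=True`` additionally applies Benjamini-Hochberg to the
    p-values before the ``passes`` filter.
    """
    background = set(background)
    dep_set = set(dep_set)
    if not dep_set <= background:
        missing = sorted(dep_set - background)[:5]
        raise ValueError(f"DEP proteins missing from background: {missing} ...")
    N = len(background)
    n = len(dep_set)
    rows = []
    for term in sorted(annotation):
        members = annotation[term] & background
        K = len(members)
        if K == 0:
            warnings.warn(f"term {term!r} has no background proteins; skipped")
            continue
        k = len(members & dep_set)
        # upper tail P(X >= k) of Hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        ef = (k / n) / (K / N) if n > 0 else np.nan
        rows.append(
            {"term": term, "k": k, "n": n, "K": K, "N": N,
             "p_value": p, "enrichment_factor": ef}
        )
    out = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "p_value", "enrichment_factor"]
    )
    if bh and len(out):
        out["p_value"] = stats.false_discovery_control(out["p_value"], method="bh")
    out["passes"] = (out["p_value"] < alpha) & (out["enrichment_factor"] > min_ef)
    return out.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)


def enrich_all(
    calls: pd.DataFrame,
    annotation: Mapping[str, set[str]],
    background: Iterable[str],
    alpha: float = 0.05,
    min_ef: float = 1.5,
) -> pd.DataFrame:
    """Enrichment per mutant and direction (up/down DEP sets tested separately)."""
    from .depcall import dep_sets

    background = set(background)
    frames = []
    for direction in ("up", "down"):
        for mutant, prots in sorted(dep_sets(calls, direction=direction).items()):
            if not prots:
                continue
            res = fisher_enrichment(prots, annotation, background, alpha, min_ef)
            res.insert(0, "direction", direction)
            res.insert(0, "mutant", mutant)
            frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["mutant", "direction", "term", "k", "n", "K", "N",
                     "p_value", "enrichment_factor", "passes"]
        )
    return pd.concat(frames, ignore_index=True)
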