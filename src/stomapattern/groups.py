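"""Within-leaf comparisons of SD, MNND and SAI across layers and positions.

The sampling design measures each leaf at several lamina sections (layers
running apex → base, positions midrib vs. margin), so comparisons between
sections are paired within leaves. This module summarizes each
species × layer × position cell (mean, median, coefficient of variation)
and tests cell differences with a within-leaf sign-flip permutation test on
the paired per-leaf differences — a self-contained, assumption-light
stand-in for a linear mixed-effects model with leaf as a random effect; the
reports label it as such. Cells that do not differ significantly share a
letter in a compact letter display.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

METRICS = ("sd", "mnnd", "sai")
_META_COLS = ("species", "leaf_id", "layer", "position")


def summarize_sections(df: pd.DataFrame) -> pd.DataFrame:
    """Tidy summary table, one row per species × layer × position × metric.

    Parameters
    ----------
    df : DataFrame
        Per-window statistics with columns ``species, leaf_id, layer,
        position, sd, mnnd, sai`` (one row per window); every
        (species, leaf, layer, position) combination may appear at most
        once.

    Returns
    -------
    DataFrame
        Columns ``species, layer, position, metric, n_leaves, mean,
        median, cv_pct``; CV% = 100 · sample SD / mean, reported to two
        decimals.
    """
    missing = [c for c in _META_COLS + METRICS if c not in df.columns]
    if missing:
        raise ValueError(f"summary input missing columns: {missing}")
    meta = df[list(_META_COLS)]
    bad = df.index[meta.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"records with missing metadata at rows: {bad}")
    dup = df.duplicated(subset=list(_META_COLS), keep=False)
    if dup.any():
        offenders = df.loc[dup, list(_META_COLS)].to_records(index=False)
        raise ValueError(
            f"duplicate (species, leaf, layer, position) records: "
            f"{list(offenders)[:10]}"
        )
    rows = []
    for (sp, layer, pos), cell in df.groupby(["species", "layer", "position"],
                                             sort=True):
        for metric in METRICS:
            v = cell[metric].to_numpy(dtype=float)
            mean = float(v.mean())
            sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
            rows.append({
                "species": sp, "layer": layer, "position": pos,
                "metric": metric, "n_leaves": int(v.size),
                "mean": mean, "median": float(np.median(v)),
                "cv_pct": round(100.0 * sd / mean, 2) if mean != 0 else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PermutationTestResult:
    """Result of a within-leaf sign-flip permutation test."""

    statistic: float          # observed mean paired difference
    p_value: float
    n_pairs: int
    n_perm: int               # permutations actually evaluated
    method: str               # "exact" (full enumeration) or "monte-carlo"


def paired_permutation_test(a: Sequence[float], b: Sequence[float],
                            n_perm: int = 9999, seed=None,
                            method: str = "auto") -> PermutationTestResult:
    """Two-sided sign-flip permutation test on paired samples.

    The statistic is T = mean(a − b). Under the null of exchangeability
    within pairs, each paired difference's sign is flipped independently;
    the two-sided p-value is (1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_perm) for
    Monte-Carlo sampling, or the exact tail proportion over all 2^n sign
    patterns when enumeration is feasible (``method="auto"`` enumerates
    whenever 2^n ≤ n_perm; the identity pattern makes the exact p-value
    strictly positive).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d arrays of equal length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired samples must be finite")
    n = a.size
    if n < 6:
        raise ValueError(f"need at least 6 complete pairs, got {n}")
    d = a - b
    t_obs = abs(d.mean())
    # tolerance so exact enumeration ties are counted as >= (float round-off)
    tol = 1e-12 * max(1.0, float(np.abs(d).max()))
    if method not in ("auto", "exact", "monte-carlo"):
        raise ValueError(f"unknown method {method!r}")
    exact = method == "exact" or (method == "auto" and 2 ** n <= n_perm)
    if exact:
        codes = np.arange(2 ** n, dtype=np.int64)
        signs = 1.0 - 2.0 * ((codes[:, None] >> np.arange(n, dtype=np.int64))
                             & 1)
        t_perm = np.abs(signs @ d) / n
        p = float(np.count_nonzero(t_perm >= t_obs - tol)) / t_perm.size
        return PermutationTestResult(float(d.mean()), p, n, t_perm.size,
                                     "exact")
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    t_perm = np.abs(signs @ d) / n
    p = (1.0 + np.count_nonzero(t_perm >= t_obs - tol)) / (1.0 + n_perm)
    return PermutationTestResult(float(d.mean()), float(p), n, n_perm,
                                 "monte-carlo")


def letter_display(names: Sequence, means: Dict, pvalues: Dict[Tuple, float],
                   alpha: float = 0.05) -> Dict:
    """Assign letters so cells not significantly different share a letter.

    Uses the transitive-closure convention: groups are the connected
    components of the "not significantly different at ``alpha``" graph, so
    if A≈B and B≈C are each non-significant, A, B and C share a letter even
    if A vs. C alone is significant. Components are lettered 'a', 'b', …
    in order of decreasing group mean.
    """
    names = list(names)
    index = {name: i for i, name in enumerate(names)}
    parent = list(range(len(names)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for (u, v), p in pvalues.items():
        if p > alpha:
            ru, rv = find(index[u]), find(index[v])
            if ru != rv:
                parent[ru] = rv
    comps: Dict[int, list] = {}
    for name in names:
        comps.setdefault(find(index[name]), []).append(name)
    ordered = sorted(
        comps.values(),
        key=lambda grp: -float(np.mean([means[n] for n in grp])),
    )
    letters = {}
    for k, grp in enumerate(ordered):
        letter = chr(ord("a") + k)
        for name in grp:
            letters[name] = letter
    return letters


def compare_levels(df: pd.DataFrame, value: str, level_col: str,
                   fixed: Optional[Dict] = None, block_col: str = "leaf_id",
                   n_perm: int = 9999, seed=None, alpha: float = 0.05,
                   adjust: str = "none"):
    """All pairwise within-leaf permutation tests across levels of a factor.

    Restricts ``df`` to rows matching ``fixed`` (e.g. one species and one
    position), pivots to one row per leaf, tests every pair of levels of
    ``level_col`` with :func:`paired_permutation_test`, and assigns letters
    with :func:`letter_display`. Leaves missing a level make the pairing
    impossible and raise an error naming them. ``adjust="holm"`` applies
    Holm's step-down correction to the p-values before lettering.

    Returns
    -------
    (pairs, letters) : (DataFrame, dict)
        Pairwise results (level_1, level_2, statistic, p_value) and the
        letter assignment per level.
    """
    sub = df
    for col, val in (fixed or {}).items():
        sub = sub[sub[col] == val]
    wide = sub.pivot(index=block_col, columns=level_col, values=value)
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(
            f"unpaired {block_col} values (missing some levels): {bad}"
        )
    levels = list(wide.columns)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rows = []
    pvals = {}
    for (u, v), child in zip(itertools.combinations(levels, 2),
                             ss.spawn(len(levels) * (len(levels) - 1) // 2)):
        res = paired_permutation_test(
            wide[u].to_numpy(), wide[v].to_numpy(),
            n_perm=n_perm, seed=child,
        )
        rows.append({"level_1": u, "level_2": v,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "method": res.method})
        pvals[(u, v)] = res.p_value
    pairs = pd.DataFrame(rows)
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(pairs["p_value"].to_numpy(), method="holm")[1]
        pairs["p_value_adj"] = adj
        pvals = {k: p for k, p in zip(pvals, adj)}
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    means = {lvl: float(wide[lvl].mean()) for lvl in levels}
    letters = letter_display(levels, means, pvals, alpha=alpha)
    return pairs, letters
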