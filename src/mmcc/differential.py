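"""Case-control differential testing on pseudobulk read totals.

For each feature within a (lineage, timepoint) stratum, reads are pooled
across case donors and across control donors and laid out as a 2x2 table::

            in feature   in all other features
    cases        a                b
    controls     c                d

Fisher's exact test (two-sided, point-probability rule) gives the p-value;
the effect is the case/control proportion ratio ``(a/(a+b)) / (c/(c+d))``.
Benjamini-Hochberg FDR is applied within each (modality, timepoint)
stratum across lineages and features (pooling across timepoints too is
available via ``bh_scope``).

Note this test pools reads across donors and therefore ignores
donor-level variation (pseudoreplication); it is exactly calibrated only
when cells of a stratum are exchangeable across donors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from mmcc.types import Pseudobulk

# Relative tie tolerance for the point-probability two-sided rule, matching
# the convention of R's fisher.test: tables with pmf <= pmf_obs * (1 + 1e-7)
# count as "as or more extreme".
_TIE_EPS = 1e-7

UP_IN_CASES = "up_in_cases"
UP_IN_CONTROLS = "up_in_controls"


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_twosided_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Two-sided Fisher exact p-values for many 2x2 tables.

    Implements the point-probability rule on the hypergeometric
    distribution conditioned on all four margins: the p-value sums the
    probabilities of every table with the same margins whose probability
    does not exceed the observed table's.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("negative cell in 2x2 table")
    n1 = a + b
    n2 = c + d
    if ((n1 == 0) | (n2 == 0)).any():
        raise ValueError("zero margin in 2x2 table")
    k_col = a + c
    p = np.empty(len(a), dtype=float)
    for i in range(len(a)):
        n1_i, n2_i, k_i = n1[i], n2[i], k_col[i]
        lo = max(0, k_i - n2_i)
        hi = min(k_i, n1_i)
        support = np.arange(lo, hi + 1)
        logpmf = (
            _log_binom(n1_i, support)
            + _log_binom(n2_i, k_i - support)
            - _log_binom(n1_i + n2_i, k_i)
        )
        log_obs = logpmf[a[i] - lo]
        mask = logpmf <= log_obs + _TIE_EPS
        p[i] = np.exp(logpmf[mask] - log_obs).sum() * np.exp(log_obs)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def proportion_ratio(a, b, c, d) -> np.ndarray:
    """Case/control proportion ratio ``(a/(a+b)) / (c/(c+d))``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a / (a + b)) / (c / (c + d))


def fisher_obs_exp(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Observed/expected Fisher test for one feature.

    Parameters are the 2x2 table entries: case reads in the feature /
    in all other features, control reads likewise.  Returns
    ``(effect, p)`` where effect is the case/control proportion ratio.
    """
    p = fisher_twosided_many([a], [b], [c], [d])[0]
    effect = float(proportion_ratio([a], [b], [c], [d])[0])
    return effect, float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _stratum_tables(
    pb: Pseudobulk, case_donors: set[str], control_donors: set[str]
) -> list[tuple[str, str, np.ndarray, np.ndarray]]:
    """Per (lineage, timepoint): pooled case and control read vectors."""
    out = []
    for (tp, lineage), sub in pb.totals.groupby(level=["timepoint", "lineage"], sort=True):
        donors = sub.index.get_level_values("donor_id")
        case_rows = sub[donors.isin(case_donors)]
        ctrl_rows = sub[donors.isin(control_donors)]
        if len(case_rows) == 0 or len(ctrl_rows) == 0:
            logging.getLogger(__name__).warning(
                "stratum (%s, %s) missing a status group; skipped", lineage, tp
            )
            continue
        out.append((lineage, tp, case_rows.sum(axis=0).to_numpy(), ctrl_rows.sum(axis=0).to_numpy()))
    return out


def run_differential(
    pb: Pseudobulk,
    samples: pd.DataFrame,
    fdr: float = 0.10,
    case_subset: list[str] | None = None,
    bh_scope: str = "timepoint",
) -> pd.DataFrame:
    """Full differential table for one modality's pseudobulk.

    Parameters
    ----------
    pb
        Pseudobulk totals for one modality.
    samples
        Donor metadata with ``status`` (case/control) and ``pair_id``.
    fdr
        BH threshold for the ``significant`` flag.
    case_subset
        Restrict the analysis to these case donors and their matched
        pair controls (used for endotype subgroup runs).
    bh_scope
        ``"timepoint"`` (default): BH within each (modality, timepoint)
        across lineages and features.  ``"all"``: BH pooled across
        timepoints as well.

    Returns
    -------
    DataFrame with columns feature_id, lineage, timepoint, modality,
    a, b, c, d, effect, direction, p, q, significant.  Features with zero
    reads in both groups for a stratum are excluded from testing and from
    the BH denominator.
    """
    cases = samples[samples["status"] == "case"]
    if case_subset is not None:
        cases = cases[cases["donor_id"].isin(case_subset)]
        missing = set(case_subset) - set(cases["donor_id"])
        if missing:
            raise ValueError(f"case_subset donors not found among cases: {sorted(missing)}")
        pair_ids = set(cases["pair_id"])
        controls = samples[(samples["status"] == "control") & samples["pair_id"].isin(pair_ids)]
        missing_pairs = pair_ids - set(controls["pair_id"])
        if missing_pairs:
            raise ValueError(f"missing matched control for pairs: {sorted(missing_pairs)}")
    else:
        controls = samples[samples["status"] == "control"]

    features = np.asarray(pb.totals.columns)
    frames = []
    for lineage, tp, case_vec, ctrl_vec in _stratum_tables(
        pb, set(cases["donor_id"]), set(controls["donor_id"])
    ):
        keep = (case_vec + ctrl_vec) > 0
        a = case_vec[keep]
        c = ctrl_vec[keep]
        b = case_vec.sum() - a
        d = ctrl_vec.sum() - c
        p = fisher_twosided_many(a, b, c, d)
        effect = proportion_ratio(a, b, c, d)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": features[keep],
                    "lineage": lineage,
                    "timepoint": tp,
                    "modality": pb.modality,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "effect": effect,
                    "direction": np.where(effect > 1, UP_IN_CASES, UP_IN_CONTROLS),
                    "p": p,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "feature_id", "lineage", "timepoint", "modality",
                "a", "b", "c", "d", "effect", "direction", "p", "q", "significant",
            ]
        )
    table = pd.concat(frames, ignore_index=True)
    if bh_scope == "timepoint":
        table["q"] = table.groupby("timepoint")["p"].transform(lambda s: bh_fdr(s.to_numpy()))
    elif bh_scope == "all":
        table["q"] = bh_fdr(table["p"].to_numpy())
    else:
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    table["significant"] = table["q"] < fdr
    return table
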