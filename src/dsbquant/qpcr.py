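"""Percent-input, fold-induction and relative-expression arithmetic for
DRIP-/ChIP-qPCR and RT-qPCR panels.

Conventions
-----------
* Percent input expresses an IP signal as a percentage of the
  dilution-corrected input: ``100 * ip / (input / input_fraction)`` where
  ``input_fraction`` is the fraction of chromatin set aside as input (it has
  no canonical default — assays differ — so it is a required argument).
* Fold induction is the ratio of cut to uncut percent-input values,
  computed per replicate and then averaged (mean +/- s.e.m. across
  experiments), not as a ratio of means.
* Relative expression follows the ddCq convention with a configurable
  amplification efficiency (default 2.0 fold/cycle).  Typical normalizers
  in this context are 7SK or 47S for damage-induced transcripts and RPPO
  for mRNAs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParameterError

ArrayLike = "float | np.ndarray"


def quantity_from_cq(cq, efficiency: float = 2.0):
    """Linear-scale abundance from a Cq value, up to a shared constant.

    ``quantity = efficiency ** (-cq)`` — one cycle earlier means
    ``efficiency``-fold more template.
    """
    if efficiency <= 1:
        raise ParameterError("efficiency must be > 1")
    return np.power(float(efficiency), -np.asarray(cq, float))


def percent_input(ip, input_, input_fraction: float):
    """IP signal as percent of the dilution-corrected input.

    ``100 * ip / (input / input_fraction)``.  ``input = 0`` yields NaN
    (flagged undefined) rather than raising, so replicate tables with a
    failed input well survive aggregation.
    """
    if not 0 < input_fraction <= 1:
        raise ParameterError("input_fraction must be in (0, 1]")
    ip = np.asarray(ip, float)
    input_ = np.asarray(input_, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(input_ > 0, 100.0 * ip / (input_ / input_fraction), np.nan)
    return out if out.ndim else float(out)


def percent_input_from_cq(ip_cq, input_cq, input_fraction: float, efficiency: float = 2.0):
    """Percent input straight from Cq values.

    Equivalent to converting both Cq values to linear quantities and
    applying :func:`percent_input`:
    ``100 * input_fraction * efficiency ** (input_cq - ip_cq)``.
    """
    return percent_input(
        quantity_from_cq(ip_cq, efficiency),
        quantity_from_cq(input_cq, efficiency),
        input_fraction,
    )


def fold_induction(cut_pi, uncut_pi):
    """Cut over uncut percent-input ratio; NaN (flagged) when uncut is 0."""
    cut_pi = np.asarray(cut_pi, float)
    uncut_pi = np.asarray(uncut_pi, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(uncut_pi > 0, cut_pi / uncut_pi, np.nan)
    return out if out.ndim else float(out)


def relative_expression(
    target_cq, norm_cq, ref_target_cq, ref_norm_cq, efficiency: float = 2.0
):
    """ddCq relative expression against a normalizer and a reference sample.

    ``efficiency ** -((target_cq - norm_cq) - (ref_target_cq - ref_norm_cq))``.
    Invariant to adding a constant to both target and normalizer Cq.
    """
    if efficiency <= 1:
        raise ParameterError("efficiency must be > 1")
    ddcq = (np.asarray(target_cq, float) - np.asarray(norm_cq, float)) - (
        np.asarray(ref_target_cq, float) - np.asarray(ref_norm_cq, float)
    )
    out = np.power(float(efficiency), -ddcq)
    return out if out.ndim else float(out)


def fold_table(measurements: pd.DataFrame, input_fraction: float) -> pd.DataFrame:
    """Per-replicate fold inductions from a long-format measurement table.

    Expects columns ``region, condition (cut/uncut), fraction (IP/input),
    replicate, quantity``.  For each (region, replicate): percent input per
    condition, then fold = cut / uncut.
    """
    needed = {"region", "condition", "fraction", "replicate", "quantity"}
    missing = needed - set(measurements.columns)
    if missing:
        raise ParameterError(f"measurement table missing columns {sorted(missing)}")
    wide = measurements.pivot_table(
        index=["region", "replicate"],
        columns=["condition", "fraction"],
        values="quantity",
        aggfunc="mean",
    )
    rows = []
    for (region, replicate), r in wide.iterrows():
        pi = {
            cond: percent_input(r[(cond, "IP")], r[(cond, "input")], input_fraction)
            for cond in ("cut", "uncut")
            if (cond, "IP") in r.index and (cond, "input") in r.index
        }
        if {"cut", "uncut"} <= pi.keys():
            rows.append(
                {
                    "region": region,
                    "replicate": replicate,
                    "percent_input_cut": pi["cut"],
                    "percent_input_uncut": pi["uncut"],
                    "fold": fold_induction(pi["cut"], pi["uncut"]),
                }
            )
    return pd.DataFrame(rows)


def summarize_folds(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- s.e.m. of per-replicate folds for each region.

    With a single replicate the s.e.m. is undefined (NaN, flagged by
    ``n = 1``).
    """
    def _sem(v):
        v = v.dropna()
        return v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan

    out = (
        folds.groupby("region")["fold"]
        .agg(n="count", mean_fold="mean", sem_fold=_sem)
        .reset_index()
    )
    return out
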