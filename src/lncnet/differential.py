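"""Two-group differential expression on log2 data, plus qPCR relative quantification.

Per probe: signed linear fold change reconstructed from log2 group means,
a Student's t-test (pooled variance by default, Welch optional), BH FDR
adjustment stratified by biotype, and the selection rule
|FC| >= fc_threshold (inclusive) AND q < fdr_threshold (exclusive).
Selected probes are ranked by ascending p within biotype and the top
``top_selected`` per biotype carry a rank.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .data_model import LNCRNA, MRNA, ExpressionMatrix
from .errors import ConsistencyError

#: Column order of the differential table written by the pipeline.
DIFFERENTIAL_COLUMNS = [
    "probe_id", "biotype", "mean_case", "mean_control", "signed_fc",
    "t_stat", "p_value", "q_value", "direction", "selected", "rank",
    "degenerate",
]


def signed_fold_change(case_values: Iterable[float],
                       control_values: Iterable[float]) -> float:
    """Signed linear fold change from log2 values.

    With linear ratio rho = 2**(mean(case) - mean(control)), returns rho
    if rho >= 1 and -1/rho otherwise, so |FC| >= 1 always and down-regulation
    is reported as a negative ratio (e.g. -2.0 for a halving).
    """
    case = np.asarray(list(case_values), dtype=float)
    control = np.asarray(list(control_values), dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("signed_fold_change requires non-empty vectors")
    rho = 2.0 ** (case.mean() - control.mean())
    return float(rho) if rho >= 1.0 else float(-1.0 / rho)


def two_sample_t(case_values: Iterable[float], control_values: Iterable[float],
                 welch: bool = False) -> tuple[float, float, bool]:
    """Two-sided two-sample t-test; returns ``(t, p, degenerate)``.

    The default is the pooled-variance Student's test with
    df = n1 + n2 - 2.  Zero pooled variance is flagged degenerate:
    equal means give (0, 1), different means give (+/-inf, 0).
    """
    case = np.asarray(list(case_values), dtype=float)
    control = np.asarray(list(control_values), dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("two_sample_t requires >= 2 observations per group")
    if welch:
        res = stats.ttest_ind(case, control, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        if math.isnan(t):  # both groups constant
            diff = case.mean() - control.mean()
            return (0.0, 1.0, True) if diff == 0 else \
                (math.copysign(math.inf, diff), 0.0, True)
        return t, p, False
    n1, n2 = case.size, control.size
    df = n1 + n2 - 2
    v1 = case.var(ddof=1)
    v2 = control.var(ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    diff = case.mean() - control.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, True
        return math.copysign(math.inf, diff), 0.0, True
    t = diff / math.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0)), False


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise mean and unbiased variance."""
    return values.mean(axis=1), values.var(axis=1, ddof=1)


def select_mask(signed_fc: np.ndarray, q_values: np.ndarray,
                config: AnalysisConfig) -> np.ndarray:
    """The differential selection rule: |FC| >= threshold and q < threshold.

    The fold-change bound is inclusive and the FDR bound exclusive, so a
    probe at exactly FC = 1.5 with q = 0.049 is selected while q = 0.05
    is not.
    """
    return (np.abs(signed_fc) >= config.fc_threshold) & \
        (q_values < config.fdr_threshold)


def call_differential(matrix: ExpressionMatrix, annot: pd.DataFrame,
                      config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-probe differential table for every annotated probe in the matrix.

    BH adjustment runs separately within each biotype (lncRNAs and mRNAs
    are treated as parallel experiments; set ``config.bh_global`` for a
    single stratum).  Selected probes are ranked by ascending p (ties:
    larger |FC| first, then probe id); the top ``config.top_selected``
    per biotype carry ranks 1..N, everything else has a missing rank.
    """
    config = config or AnalysisConfig()
    probes = [p for p in matrix.probe_ids if p in annot.index]
    values = matrix.values.loc[probes]
    case = values[matrix.case_samples].to_numpy(dtype=float)
    control = values[matrix.control_samples].to_numpy(dtype=float)
    n1, n2 = case.shape[1], control.shape[1]
    df_t = n1 + n2 - 2

    m_case, v_case = _group_stats(case)
    m_control, v_control = _group_stats(control)
    diff = m_case - m_control

    if config.welch:
        t_stat, p_value = stats.ttest_ind(case, control, axis=1, equal_var=False)
        degenerate = ~np.isfinite(t_stat)
    else:
        pooled = ((n1 - 1) * v_case + (n2 - 1) * v_control) / df_t
        degenerate = pooled == 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = diff / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        p_value = 2.0 * stats.t.sf(np.abs(t_stat), df_t)
    sentinel = np.where(diff == 0, 0.0, np.where(diff > 0, np.inf, -np.inf))
    t_stat = np.where(degenerate, sentinel, t_stat)
    p_value = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p_value)
    p_value = np.clip(p_value, 0.0, 1.0)

    ratio = 2.0 ** diff
    signed_fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)

    biotype = annot.loc[probes, "biotype"].to_numpy()
    q_value = np.empty_like(p_value)
    if config.bh_global:
        q_value[:] = bh_adjust(p_value)
    else:
        for bt in (MRNA, LNCRNA):
            idx = biotype == bt
            if idx.any():
                q_value[idx] = bh_adjust(p_value[idx])

    selected = select_mask(signed_fc, q_value, config)
    direction = np.where(diff > 0, "up", np.where(diff < 0, "down", "none"))

    records = pd.DataFrame({
        "probe_id": probes,
        "biotype": biotype,
        "mean_case": m_case,
        "mean_control": m_control,
        "signed_fc": signed_fc,
        "t_stat": t_stat,
        "p_value": p_value,
        "q_value": q_value,
        "direction": direction,
        "selected": selected,
        "rank": pd.array([pd.NA] * len(probes), dtype="Int64"),
        "degenerate": degenerate,
    })

    for bt in (MRNA, LNCRNA):
        sel = records[(records["biotype"] == bt) & records["selected"]]
        order = sel.assign(abs_fc=sel["signed_fc"].abs()).sort_values(
            ["p_value", "abs_fc", "probe_id"], ascending=[True, False, True],
            kind="mergesort")
        top = order.index[: config.top_selected]
        records.loc[top, "rank"] = np.arange(1, len(top) + 1)
    return records


def delta_delta_ct(target_ct: Mapping[str, float],
                   reference_cts: Mapping[str, Mapping[str, float]],
                   groups: Mapping[str, str]) -> pd.Series:
    """Relative quantification by the delta-delta-Ct method.

    ``reference_cts`` maps reference-gene name -> {sample: Ct}; multiple
    reference genes are combined by the arithmetic mean of their Ct values
    (the geometric mean of expression).  The control group is the
    calibrator: its mean delta-Ct is subtracted and the relative quantity
    is 2**(-delta-delta-Ct), so the control group averages at 1 on the
    log scale.
    """
    samples = list(target_ct)
    if not reference_cts:
        raise ValueError("at least one reference gene is required")
    ref_means = {}
    for s in samples:
        vals = []
        for gene, cts in reference_cts.items():
            if s not in cts:
                raise ConsistencyError(
                    f"sample {s!r} missing reference measurement for {gene!r}")
            vals.append(cts[s])
        ref_means[s] = float(np.mean(vals))
    delta = pd.Series({s: target_ct[s] - ref_means[s] for s in samples})
    controls = [s for s in samples if groups.get(s) == "control"]
    if not controls:
        raise ConsistencyError("no control samples to calibrate against")
    ddct = delta - delta[controls].mean()
    return 2.0 ** (-ddct)
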