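"""Signal calling, normalization, quantitation, and community statistics.

The analysis chain applied to a raw probe-intensity table:

1. **Positive calling** — per subarray, background mean and standard
   deviation (sample sd, n−1) are estimated from the negative controls;
   a spot's SNR is (raw − background mean) / background sd and a spot is
   positive iff SNR > 2 (strict). Net intensity is raw minus the subarray
   negative-control mean, floored at 0.
2. **PM/MM calling** — PM/MM net-intensity ratio (nets floored at 1
   intensity unit to avoid division by zero); a pair is a specific
   positive when the PM spot itself is a positive call and the ratio
   exceeds 1.3.
3. **CORS normalization** — each array's intensities are rescaled by
   (global mean CORS intensity)/(array mean CORS intensity), equalizing
   the reference-standard means across arrays while preserving
   within-array ratios exactly.
4. **Quantitation** — per-probe least-squares fit of log10(mean net
   intensity across replicates) on log10(DNA mass) over the dilution
   points where the probe is detected, plus the same fit for the total
   signal of all detected spots.
5. **Community statistics** — per-sample functional gene richness,
   Shannon–Weaver H′ (natural log, normalized intensity as the abundance
   proxy), evenness H′/ln(richness); per-gene between-group relative
   difference (mean₁ − mean₂)/max(mean₁, mean₂) with a two-sided
   Mann–Whitney U test, significant at two-tailed p < 0.1. No
   multiple-testing correction by default (a Benjamini–Hochberg option is
   provided).

A gene (probe) is "detected" in a sample when it is positive in a
majority of replicates (>= ceil((n+1)/2), i.e. 2 of 3). All rules are
configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError, DomainError, PairingError
from .hyb_sim import SignalMatrix
from .probe_design import MismatchPair

logger = logging.getLogger("fgarray")

__all__ = [
    "CallTable",
    "QuantFit",
    "compute_calls",
    "pm_mm_calls",
    "normalize_cors",
    "fit_quantitation",
    "relative_difference",
    "community_stats",
]

#: net intensities are floored at this value for ratios and log transforms
NET_FLOOR = 1.0


@dataclass
class CallTable:
    """Per-spot calls: one row per probe × sample × replicate with
    net intensity, SNR, and the positive flag; ratio columns are filled by
    :func:`pm_mm_calls` for PM probes."""

    data: pd.DataFrame
    snr_threshold: float = 2.0
    ratio_threshold: float | None = None


def compute_calls(signals: SignalMatrix, snr_threshold: float = 2.0) -> CallTable:
    """Call positive spots against per-subarray negative-control background.

    Every subarray of every array must contain >= 2 negative-control
    spots. If the background sd is zero the SNR is undefined: the spot is
    flagged (``snr`` = NaN) and treated as positive iff raw > background
    mean (logged).
    """
    df = signals.data.copy()
    parts = []
    for (sample, rep, sub), grp in df.groupby(["sample", "replicate", "subarray"]):
        neg = grp.loc[grp["probe_class"] == "negative_control", "intensity"]
        if len(neg) < 2:
            raise ContractError(
                f"subarray {sub} of array ({sample}, {rep}) has "
                f"{len(neg)} negative controls; need >= 2 for background estimation"
            )
        bg_mean = float(neg.mean())
        bg_sd = float(neg.std(ddof=1))
        out = grp.copy()
        out["net"] = np.maximum(out["intensity"] - bg_mean, 0.0)
        if bg_sd > 0:
            out["snr"] = (out["intensity"] - bg_mean) / bg_sd
            out["positive"] = out["snr"] > snr_threshold
        else:
            logger.warning(
                "array (%s, %s) subarray %s: zero background sd; "
                "falling back to raw > background mean", sample, rep, sub,
            )
            out["snr"] = np.nan
            out["positive"] = out["intensity"] > bg_mean
        out["bg_mean"] = bg_mean
        out["bg_sd"] = bg_sd
        parts.append(out)
    data = pd.concat(parts, ignore_index=True)
    return CallTable(data=data, snr_threshold=snr_threshold)


def pm_mm_calls(
    calls: CallTable,
    pairs: Sequence[MismatchPair] | Sequence[tuple],
    ratio_threshold: float = 1.3,
) -> pd.DataFrame:
    """PM/MM ratios per pair and array.

    ratio = net(PM)/net(MM) with both nets floored at 1 intensity unit;
    ``ratio_positive`` requires the PM spot to be a positive call *and*
    the ratio to exceed the threshold — the ratio alone is meaningless
    when neither probe rises above background.
    """
    df = calls.data.set_index(["probe_id", "sample", "replicate"])
    rows = []
    for pair in pairs:
        pm, mm = (pair.pm, pair.mm) if isinstance(pair, MismatchPair) else pair
        try:
            pm_rows = df.loc[pm.probe_id]
            mm_rows = df.loc[mm.probe_id]
        except KeyError as e:
            raise PairingError(f"PM/MM pair member {e} absent from the call table") from e
        joined = pm_rows.join(mm_rows, lsuffix="_pm", rsuffix="_mm", how="inner")
        if len(joined) != len(pm_rows):
            raise PairingError(
                f"pair {pm.probe_id}/{mm.probe_id}: arrays do not match up"
            )
        for (sample, rep), r in joined.iterrows():
            ratio = max(r["net_pm"], NET_FLOOR) / max(r["net_mm"], NET_FLOOR)
            rows.append(
                (
                    pm.probe_id, mm.probe_id, sample, rep,
                    r["net_pm"], r["net_mm"], ratio,
                    bool(r["positive_pm"]) and ratio > ratio_threshold,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "pm_probe_id", "mm_probe_id", "sample", "replicate",
            "net_pm", "net_mm", "ratio", "ratio_positive",
        ],
    )
    calls.ratio_threshold = ratio_threshold
    return out


def normalize_cors(signals: SignalMatrix) -> SignalMatrix:
    """Scale every array by (global mean CORS)/(array mean CORS).

    Idempotent; preserves within-array ratios exactly; after scaling the
    CORS means agree across arrays.
    """
    df = signals.data
    cors = df[df["probe_class"] == "cors_control"]
    if cors.empty:
        raise ContractError("no CORS probes present; cannot normalize")
    per_array = cors.groupby(["sample", "replicate"])["intensity"].mean()
    arrays = df.groupby(["sample", "replicate"]).ngroups
    if len(per_array) != arrays or (per_array <= 0).any():
        raise ContractError("every array needs >= 1 CORS spot with signal")
    global_mean = float(per_array.mean())
    factors = global_mean / per_array
    out = df.copy()
    keys = list(zip(out["sample"], out["replicate"]))
    out["intensity"] = out["intensity"].to_numpy() * factors.loc[keys].to_numpy()
    return SignalMatrix(
        data=out,
        provenance={**signals.provenance, "normalized": "cors"},
    )


@dataclass
class QuantFit:
    """Dilution-series fits of log10 intensity on log10 mass."""

    per_probe: pd.DataFrame  # probe_id, slope, intercept, pearson_r, n_points
    total_slope: float
    total_intercept: float
    total_r: float
    total_n: int
    n_excluded: int  # probes detected at fewer than min_points
    saturated_flagged: list[str] = field(default_factory=list)


def _majority(n_replicates: int) -> int:
    return n_replicates // 2 + 1


def detection_table(
    calls: CallTable, min_positive_replicates: int | None = None
) -> pd.DataFrame:
    """Per probe × sample: detected flag (positive in >= the required
    number of replicates, majority by default) and mean net intensity."""
    grouped = calls.data.groupby(["probe_id", "probe_class", "sample"])
    agg = grouped.agg(
        n_pos=("positive", "sum"),
        n_rep=("positive", "size"),
        mean_net=("net", "mean"),
        mean_raw=("intensity", "mean"),
    ).reset_index()
    if min_positive_replicates is None:
        agg["detected"] = agg["n_pos"] >= agg["n_rep"].map(_majority)
    else:
        agg["detected"] = agg["n_pos"] >= min_positive_replicates
    return agg


def fit_quantitation(
    signals: SignalMatrix,
    masses: Mapping[str, float],
    snr_threshold: float = 2.0,
    min_points: int = 3,
    min_positive_replicates: int | None = None,
    saturation: float | None = None,
) -> QuantFit:
    """Fit the dose response of a dilution series.

    ``masses`` maps sample name → DNA mass (ng). Per probe, log10(mean
    net across replicates) is regressed on log10(mass) over the samples
    where the probe is detected; probes detected at fewer than
    ``min_points`` samples are excluded and counted. The total-signal fit
    sums net intensity over all detected spots per sample. Probes whose
    mean raw intensity reaches ``saturation`` at any included point are
    flagged (the ceiling biases the slope downward).
    """
    if len(masses) < 3:
        raise DomainError("a dilution series needs >= 3 points")
    vals = list(masses.values())
    if any(m <= 0 for m in vals):
        raise DomainError("masses must be positive")
    if len(set(vals)) == 1:
        raise DomainError("degenerate series: all masses equal")
    calls = compute_calls(signals, snr_threshold)
    det = detection_table(calls, min_positive_replicates)
    det = det[det["sample"].isin(masses)]
    det["log_mass"] = np.log10([masses[s] for s in det["sample"]])

    rows = []
    n_excluded = 0
    saturated: list[str] = []
    biological = det[~det["probe_class"].isin(["negative_control", "cors_control"])]
    for probe_id, grp in biological.groupby("probe_id"):
        pts = grp[grp["detected"]]
        if len(pts) < min_points:
            n_excluded += 1
            continue
        x = pts["log_mass"].to_numpy()
        y = np.log10(np.maximum(pts["mean_net"].to_numpy(), NET_FLOOR))
        fit = sps.linregress(x, y)
        if saturation is not None and (pts["mean_raw"] >= saturation).any():
            saturated.append(probe_id)
        rows.append((probe_id, fit.slope, fit.intercept, fit.rvalue, len(pts)))
    per_probe = pd.DataFrame(
        rows, columns=["probe_id", "slope", "intercept", "pearson_r", "n_points"]
    )

    detected = biological[biological["detected"]]
    totals = detected.groupby("sample")["mean_net"].sum()
    totals = totals[totals > 0]
    if len(totals) >= 3:
        x = np.log10([masses[s] for s in totals.index])
        y = np.log10(totals.to_numpy())
        tfit = sps.linregress(x, y)
        total = (tfit.slope, tfit.intercept, tfit.rvalue, len(totals))
    else:
        total = (math.nan, math.nan, math.nan, len(totals))
    return QuantFit(
        per_probe=per_probe,
        total_slope=total[0],
        total_intercept=total[1],
        total_r=total[2],
        total_n=total[3],
        n_excluded=n_excluded,
        saturated_flagged=saturated,
    )


def relative_difference(mean1: float, mean2: float) -> float:
    """Between-group abundance contrast: (mean₁ − mean₂) divided by the
    higher mean. In [−1, 1] for nonnegative means; 0 when both are 0."""
    if mean1 < 0 or mean2 < 0:
        raise DomainError("relative difference is defined for nonnegative means")
    hi = max(mean1, mean2)
    if hi == 0:
        return 0.0
    return (mean1 - mean2) / hi


def community_stats(
    calls: CallTable,
    normalized: SignalMatrix,
    group_labels: Mapping[str, str],
    alpha: float = 0.1,
    bh_correct: bool = False,
    min_positive_replicates: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-sample diversity and per-gene between-group comparisons.

    Returns ``{"per_sample": ..., "per_gene": ...}``. Abundance of a
    detected gene is its mean CORS-normalized net intensity across
    replicates; undetected genes count as absent (abundance 0). Samples
    with richness 0 get missing H′/evenness. Group tests need >= 3
    samples per group (pairs failing that are skipped with a warning);
    significance is two-sided Mann–Whitney p < ``alpha`` (default 0.1,
    i.e. one-tailed 0.05), optionally Benjamini–Hochberg corrected.
    """
    norm_calls = compute_calls(normalized, calls.snr_threshold)
    det = detection_table(norm_calls, min_positive_replicates)
    det = det[~det["probe_class"].isin(
        ["negative_control", "cors_control", "mm_control"]
    )].copy()
    det["abundance"] = np.where(det["detected"], det["mean_net"], 0.0)

    per_sample_rows = []
    for sample, grp in det.groupby("sample"):
        ab = grp.loc[grp["detected"], "abundance"].to_numpy()
        ab = ab[ab > 0]
        richness = int(grp["detected"].sum())
        if richness == 0 or ab.sum() == 0:
            h = ev = math.nan
        else:
            p = ab / ab.sum()
            h = float(-(p * np.log(p)).sum())
            ev = h / math.log(richness) if richness > 1 else math.nan
        per_sample_rows.append(
            (sample, group_labels.get(sample, ""), richness, h, ev)
        )
    per_sample = pd.DataFrame(
        per_sample_rows,
        columns=["sample", "group", "richness", "shannon", "evenness"],
    )

    wide = det.pivot_table(index="probe_id", columns="sample", values="abundance")
    groups: dict[str, list[str]] = {}
    for s in wide.columns:
        g = group_labels.get(s)
        if g is not None:
            groups.setdefault(g, []).append(s)
    gene_rows = []
    names = sorted(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            g1, g2 = names[i], names[j]
            if len(groups[g1]) < 3 or len(groups[g2]) < 3:
                logger.warning(
                    "groups %s/%s have <3 samples; U test skipped", g1, g2
                )
                continue
            for probe_id, row in wide.iterrows():
                a = row[groups[g1]].to_numpy(dtype=float)
                b = row[groups[g2]].to_numpy(dtype=float)
                m1, m2 = float(np.mean(a)), float(np.mean(b))
                rd = relative_difference(m1, m2)
                if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                    p = 1.0  # identical constant samples: no evidence
                else:
                    p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                gene_rows.append((probe_id, g1, g2, m1, m2, rd, p))
    per_gene = pd.DataFrame(
        gene_rows,
        columns=["probe_id", "group1", "group2", "mean1", "mean2",
                 "relative_difference", "p_value"],
    )
    if not per_gene.empty:
        if bh_correct:
            p = per_gene["p_value"].to_numpy()
            order = np.argsort(p)
            ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
            adj = np.minimum.accumulate(ranked[::-1])[::-1]
            q = np.empty_like(adj)
            q[order] = np.minimum(adj, 1.0)
            per_gene["p_adjusted"] = q
            per_gene["significant"] = per_gene["p_adjusted"] < alpha
        else:
            per_gene["significant"] = per_gene["p_value"] < alpha
    return {"per_sample": per_sample, "per_gene": per_gene}
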