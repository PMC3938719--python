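"""Quantitative assay computations: qRT-PCR, ChIP-qPCR and dual-reporter.

Three standard formulas, each with its replicate-aggregation convention:

* Relative quantification: RQ = 2^-dCt with dCt = Ct(target) - Ct(reference),
  assuming a doubling of product per PCR cycle.  Ct replicates are averaged
  on the Ct (log) scale before exponentiation, matching the additive error
  structure of threshold cycles.  An amplification-efficiency parameter
  (default 2.0) is exposed for sensitivity checks only.
* ChIP-qPCR percent input: the input Ct is first adjusted for the input
  dilution (Ct_input - log2(1/input_fraction), i.e. the Ct the full input
  would have produced), then percent = 100 * 2^(adjusted_input - Ct_IP).
* Dual-luciferase fold induction: firefly is normalized to the co-transfected
  Renilla control per well, then the induced ratio is divided by the
  uninduced ratio.  Replicate wells are averaged on the ratio scale.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CT_FLAG_THRESHOLD = 40.0  # cycles; near no-amplification


def _check_ct(*cts: float) -> None:
    for ct in cts:
        if not math.isfinite(ct) or ct <= 0:
            raise ValueError(f"Ct value must be finite and positive, got {ct}")
        if ct >= CT_FLAG_THRESHOLD:
            logger.warning("Ct %.2f >= %.0f: near no-amplification", ct, CT_FLAG_THRESHOLD)


def relative_quantity(
    ct_target: float, ct_reference: float, efficiency: float = 2.0
) -> float:
    """RQ = efficiency^-(Ct_target - Ct_reference); 1.0 when the Cts match."""
    _check_ct(ct_target, ct_reference)
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1.0")
    return efficiency ** -(ct_target - ct_reference)


def fold_change(rq_sample: float, rq_baseline: float) -> float:
    """Expression fold change of a sample relative to a baseline RQ."""
    if rq_baseline <= 0:
        raise ValueError("baseline RQ must be positive")
    return rq_sample / rq_baseline


def percent_input(
    ct_ip: float, ct_input: float, input_fraction: float = 1.0
) -> float:
    """ChIP enrichment as a percentage of starting chromatin.

    `input_fraction` is the fraction of chromatin used for the input
    measurement (e.g. 0.01 for a 1% input); its dilution is removed from the
    input Ct before comparison.  Values above 100% are returned but warned
    about, since they signal an inverted Ct pair.
    """
    _check_ct(ct_ip, ct_input)
    if not 0 < input_fraction <= 1:
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    adjusted_input = ct_input - math.log2(1.0 / input_fraction)
    percent = 100.0 * 2.0 ** (adjusted_input - ct_ip)
    if percent > 100.0:
        logger.warning(
            "percent input %.1f%% exceeds 100%%: IP Ct below adjusted input Ct",
            percent,
        )
    return percent


def fold_induction(
    firefly_induced: float,
    renilla_induced: float,
    firefly_uninduced: float,
    renilla_uninduced: float,
) -> float:
    """Renilla-normalized reporter activity, induced over uninduced."""
    if renilla_induced <= 0 or renilla_uninduced <= 0:
        raise ValueError("Renilla normalizer readings must be positive")
    if firefly_uninduced <= 0:
        raise ValueError("uninduced firefly reading must be positive")
    if firefly_induced < 0:
        raise ValueError("firefly readings cannot be negative")
    return (firefly_induced / renilla_induced) / (
        firefly_uninduced / renilla_uninduced
    )


# ---------------------------------------------------------------------------
# Table-level interfaces (TSV-shaped DataFrames in, tidy results out)
# ---------------------------------------------------------------------------

def rq_table(samples: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Per-sample RQ from replicate Ct pairs.

    Expects columns sample_id, replicate_id, ct_target, ct_reference.
    Replicate Cts are averaged per sample before RQ.
    """
    required = {"sample_id", "ct_target", "ct_reference"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    grouped = samples.groupby("sample_id", sort=False)[
        ["ct_target", "ct_reference"]
    ].mean()
    out = grouped.reset_index()
    out["delta_ct"] = out["ct_target"] - out["ct_reference"]
    out["rq"] = [
        relative_quantity(t, r, efficiency)
        for t, r in zip(out["ct_target"], out["ct_reference"])
    ]
    return out


def percent_input_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-row percent input; expects ct_ip, ct_input, input_fraction columns."""
    required = {"ct_ip", "ct_input", "input_fraction"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = samples.copy()
    out["percent_input"] = [
        percent_input(ip, inp, f)
        for ip, inp, f in zip(out["ct_ip"], out["ct_input"], out["input_fraction"])
    ]
    return out


def fold_induction_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-construct fold induction from replicate firefly/Renilla wells.

    Expects columns construct_id, condition ("induced"/"uninduced"), firefly,
    renilla.  Per-well ratios are averaged within each condition, then the
    induced mean ratio is divided by the uninduced mean ratio.
    """
    required = {"construct_id", "condition", "firefly", "renilla"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (samples["renilla"] <= 0).any():
        raise ValueError("Renilla normalizer readings must be positive")
    work = samples.assign(ratio=samples["firefly"] / samples["renilla"])
    rows = []
    for construct, grp in work.groupby("construct_id", sort=False):
        means = grp.groupby("condition")["ratio"].mean()
        if "induced" not in means or "uninduced" not in means:
            raise ValueError(
                f"construct {construct}: needs both induced and uninduced wells"
            )
        if means["uninduced"] <= 0:
            raise ValueError(f"construct {construct}: zero uninduced activity")
        rows.append(
            (
                construct,
                means["induced"],
                means["uninduced"],
                means["induced"] / means["uninduced"],
            )
        )
    return pd.DataFrame(
        rows,
        columns=["construct_id", "ratio_induced", "ratio_uninduced", "fold_induction"],
    )


def geometric_mean(values) -> float:
    """Geometric mean of positive values (fold changes live on a log scale)."""
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))
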