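"""Relative expression quantification from qPCR Cq tables (Livak ΔΔCT method).

Replicate quantification cycles are averaged per (sample, gene); values at or
beyond the detection limit (Cq >= 34 by default) are treated as non-detects
and propagate. ΔCT normalises each target against one or more reference
genes (mean reference Cq), ΔΔCT subtracts the calibrator sample's ΔCT, and
relative expression is 2^-ΔΔCT. Calls with relative expression at or below a
low-expression cutoff (default 0.10) are binned as "low".

The low-expression rule is applied on the 2^-ΔΔCT scale by default; a raw
ΔΔCT threshold is available (``threshold_on='ddct'``) since a cutoff quoted as
"ΔΔCT <= 0.10" is ambiguous between the two scales and only the fold-change
reading yields a *low*-expression bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

DETECTION_LIMIT_CQ = 34.0
LOW_EXPRESSION_CUTOFF = 0.10


@dataclass
class ExpressionCall:
    gene: str
    sample: str
    delta_ct: float | None
    delta_delta_ct: float | None
    relative_expression: float | None
    bin: str  # 'nondetect' | 'low' | 'expressed'
    flag: str = ""


def read_cq_table(path) -> pd.DataFrame:
    """TSV with columns sample, gene, cq (one row per replicate; cq may be 'ND')."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "gene", "cq"} - set(df.columns)
    if missing:
        raise ValidationError(f"Cq table missing columns {sorted(missing)}")
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    return df


def quantify(
    cq_table: pd.DataFrame,
    reference_gene: str | list[str],
    calibrator_sample: str,
    *,
    detection_limit: float = DETECTION_LIMIT_CQ,
    low_cutoff: float = LOW_EXPRESSION_CUTOFF,
    threshold_on: str = "relative",  # 'relative' or 'ddct'
) -> list[ExpressionCall]:
    """ΔΔCT quantification of every (gene, sample) against a calibrator sample.

    ``reference_gene`` may be one gene or a list (their mean Cq normalises).
    Samples whose reference genes are undetected are flagged, not dropped.
    """
    refs = [reference_gene] if isinstance(reference_gene, str) else list(reference_gene)
    if threshold_on not in ("relative", "ddct"):
        raise ValidationError("threshold_on must be 'relative' or 'ddct'")
    df = cq_table.copy()
    if (df["cq"].dropna() <= 0).any():
        raise ValidationError("Cq values must be positive")
    mean_cq = df.groupby(["sample", "gene"])["cq"].mean()
    # non-detect: at/beyond the limit, or missing entirely
    detected = mean_cq < detection_limit

    def ref_ct(sample):
        vals = []
        for r in refs:
            key = (sample, r)
            if key not in mean_cq.index or not detected.get(key, False):
                return None
            vals.append(mean_cq[key])
        return float(np.mean(vals))

    samples = sorted(df["sample"].unique())
    genes = sorted(g for g in df["gene"].unique() if g not in refs)
    if calibrator_sample not in samples:
        raise ValidationError(f"calibrator sample {calibrator_sample!r} not in table")

    ref_by_sample = {s: ref_ct(s) for s in samples}

    def dct(sample, gene):
        key = (sample, gene)
        if key not in mean_cq.index or not detected.get(key, False):
            return None, "nondetect"
        if ref_by_sample[sample] is None:
            return None, "missing-reference"
        return float(mean_cq[key]) - ref_by_sample[sample], ""

    calls = []
    for gene in genes:
        dct_cal, cal_flag = dct(calibrator_sample, gene)
        for sample in samples:
            d, flag = dct(sample, gene)
            if d is None or dct_cal is None:
                calls.append(
                    ExpressionCall(
                        gene, sample, d, None, None,
                        bin="nondetect" if (flag == "nondetect" or cal_flag == "nondetect")
                        else "nondetect",
                        flag=flag or (f"calibrator:{cal_flag}" if cal_flag else ""),
                    )
                )
                continue
            ddct = d - dct_cal
            rel = float(2.0 ** (-ddct))
            crit = ddct if threshold_on == "ddct" else rel
            # <= with a tiny relative guard so the boundary survives the
            # round trip through log2/exp2
            at_cutoff = np.isclose(crit, low_cutoff, rtol=1e-12, atol=0.0)
            bin_ = "low" if (crit <= low_cutoff or at_cutoff) else "expressed"
            calls.append(ExpressionCall(gene, sample, d, ddct, rel, bin_))
    return calls


def calls_to_table(calls: list[ExpressionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "sample": [c.sample for c in calls],
            "delta_ct": [c.delta_ct for c in calls],
            "delta_delta_ct": [c.delta_delta_ct for c in calls],
            "relative_expression": [c.relative_expression for c in calls],
            "bin": [c.bin for c in calls],
            "flag": [c.flag for c in calls],
        }
    )
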