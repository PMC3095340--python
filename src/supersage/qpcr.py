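"""Comparative-ΔCt (ΔΔCt) relative quantification for qPCR time courses.

Target-gene cycle thresholds are normalized within each sample against a
reference gene (ΔCt = Ct_target - Ct_reference), then against the mean
ΔCt of the calibrator samples (ΔΔCt), and expressed as fold change
2^(−ΔΔCt). Amplification efficiency is fixed at 2, the comparative
method's assumption. Because the calibrator ΔCts are averaged on the Ct
(log) scale, the *geometric* mean fold at the calibrator timepoint is 1
by construction; with identical calibrator replicates every calibrator
fold is exactly 1.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

CT_COLUMNS = ["sample_id", "timepoint", "treatment", "gene", "ct", "replicate"]


def read_ct_tsv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    return df


def _validate(df: pd.DataFrame) -> None:
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if (df["replicate"] < 1).any():
        raise ValueError("replicate indices start at 1")


def relative_expression(
    ct_table: pd.DataFrame,
    gene: str,
    reference_gene: str = "NaeEF1A",
    calibrator_timepoint: float = 0,
) -> pd.DataFrame:
    """Per-sample fold change of ``gene`` relative to the calibrator.

    Every target measurement must have a reference-gene Ct in the same
    sample (paired by ``sample_id``); a missing reference raises an error
    naming the sample. Calibrator samples are those at
    ``calibrator_timepoint`` (any treatment: the unelicited time-0 leaf
    is treatment-agnostic).
    """
    _validate(ct_table)
    target = ct_table[ct_table["gene"] == gene]
    if len(target) == 0:
        raise ValueError(f"no Ct measurements for gene {gene!r}")
    reference = ct_table[ct_table["gene"] == reference_gene].set_index("sample_id")[
        "ct"
    ]
    if reference.index.has_duplicates:
        raise ValueError("multiple reference-gene Cts for one sample")
    missing = [s for s in target["sample_id"] if s not in reference.index]
    if missing:
        raise ValueError(
            f"samples missing a reference Ct for {reference_gene!r}: {missing}"
        )
    delta_ct = target["ct"].to_numpy() - reference.loc[
        target["sample_id"]
    ].to_numpy()
    out = target[["sample_id", "timepoint", "treatment", "replicate"]].copy()
    out["gene"] = gene
    out["delta_ct"] = delta_ct
    calibrator = out["timepoint"] == calibrator_timepoint
    if not calibrator.any():
        raise ValueError(
            f"no calibrator samples at timepoint {calibrator_timepoint}"
        )
    ddct = out["delta_ct"] - out.loc[calibrator, "delta_ct"].mean()
    out["fold"] = 2.0 ** (-ddct)
    return out.reset_index(drop=True)


def summarize_replicates(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of fold changes per timepoint and treatment.

    Requires at least two replicates per group (the standard error of a
    single measurement is undefined).
    """
    grouped = folds.groupby(["gene", "treatment", "timepoint"], sort=True)["fold"]
    n = grouped.size()
    if (n < 2).any():
        offenders = n[n < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 replicates: {offenders}")
    summary = pd.DataFrame(
        {
            "mean_fold": grouped.mean(),
            "se": grouped.std(ddof=1) / np.sqrt(n),
            "n": n,
        }
    ).reset_index()
    return summary
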