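"""Relative quantification by the 2^-ddCt method and RNA-seq concordance.

ddCt = (Ct_target - Ct_reference)_test - (Ct_target - Ct_reference)_calibrator,
with Ct replicates averaged before differencing and amplification efficiency
assumed to be exactly 2 (one cycle per doubling). The fold change reported is
2^-ddCt and log2fc = -ddCt, oriented test over calibrator (sterile over
fertile by default, matching the DE fold-change orientation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["delta_delta_ct", "concordance"]

_REQUIRED_COLS = {"gene", "condition", "replicate", "target_ct", "reference_ct"}


def delta_delta_ct(ct_table: pd.DataFrame, calibrator_condition: str = "F") -> pd.DataFrame:
    """Per-gene ddCt records from a tidy Ct table.

    ``ct_table`` needs columns gene, condition, replicate, target_ct,
    reference_ct, with the reference-gene Ct measured alongside each target
    reaction. Every gene must have at least one replicate in the calibrator
    and one in the test condition.
    """
    missing = _REQUIRED_COLS - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if (ct_table[["target_ct", "reference_ct"]].to_numpy() < 0).any():
        raise ValueError("negative Ct value")
    conditions = set(ct_table["condition"].unique())
    if calibrator_condition not in conditions:
        raise ValueError(f"calibrator condition {calibrator_condition!r} absent from table")
    test_conditions = sorted(conditions - {calibrator_condition})
    if len(test_conditions) != 1:
        raise ValueError("expected exactly one test condition besides the calibrator")
    test = test_conditions[0]

    means = ct_table.groupby(["gene", "condition"])[["target_ct", "reference_ct"]].mean()
    rows = []
    for gene in ct_table["gene"].unique():
        try:
            cal = means.loc[(gene, calibrator_condition)]
            tst = means.loc[(gene, test)]
        except KeyError as exc:
            raise ValueError(f"gene {gene!r} lacks replicates in one condition") from exc
        delta_cal = cal["target_ct"] - cal["reference_ct"]
        delta_test = tst["target_ct"] - tst["reference_ct"]
        ddct = delta_test - delta_cal
        rows.append(
            {
                "gene": gene,
                "target_ct_calibrator": cal["target_ct"],
                "reference_ct_calibrator": cal["reference_ct"],
                "target_ct_test": tst["target_ct"],
                "reference_ct_test": tst["reference_ct"],
                "delta_ct_calibrator": delta_cal,
                "delta_ct_test": delta_test,
                "delta_delta_ct": ddct,
                "fold": 2.0**-ddct,
                "log2fc": -ddct,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def concordance(qpcr_records: pd.DataFrame, de_results: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Gene-wise agreement between qPCR and RNA-seq log2 fold changes.

    Returns the merged per-gene table (both log2fc columns plus a
    ``sign_agree`` flag) and a summary with the concordant fraction and the
    Pearson correlation across genes. Genes with log2fc exactly 0 on either
    platform count as concordant only if both are 0.
    """
    shared = qpcr_records.index.intersection(de_results.index)
    if shared.empty:
        raise ValueError("no shared genes between qPCR and RNA-seq tables")
    table = pd.DataFrame(
        {
            "qpcr_log2fc": qpcr_records.loc[shared, "log2fc"],
            "rnaseq_log2fc": de_results.loc[shared, "log2fc"],
        }
    )
    table["sign_agree"] = np.sign(table["qpcr_log2fc"]) == np.sign(table["rnaseq_log2fc"])
    if len(table) >= 2 and table["qpcr_log2fc"].std() > 0 and table["rnaseq_log2fc"].std() > 0:
        r = float(np.corrcoef(table["qpcr_log2fc"], table["rnaseq_log2fc"])[0, 1])
    else:
        r = float("nan")
    summary = {
        "n_genes": int(len(table)),
        "sign_agreement": float(table["sign_agree"].mean()),
        "pearson_r": r,
    }
    return table, summary
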