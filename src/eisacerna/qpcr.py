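"""Relative qPCR quantification (ΔΔCT) and the mature/pre-mRNA stability index.

ΔCT = CT(target) − CT(reference gene); ΔΔCT subtracts the mean control ΔCT;
the fold change is efficiency^(−ΔΔCT) with perfect doubling (efficiency 2)
as default. The stability index divides the mature-transcript fold change by
the pre-mRNA fold change: 1 means the change is purely transcriptional,
values above 1 indicate stabilization of the mature transcript.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cerna import _pearson_table

__all__ = ["ddct_fold_change", "stability_index", "validate_correlation"]

CT_COLUMNS = ["sample_id", "target_gene", "reference_gene",
              "ct_target", "ct_reference", "condition"]


def _check_ct(table: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    ct = table[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if np.isnan(ct).any():
        raise ValueError("missing CT values (reference required for every sample)")
    if ((ct <= 0) | (ct >= 45)).any():
        raise ValueError("CT values must lie in (0, 45) cycles")


def ddct_fold_change(
    table: pd.DataFrame,
    control_label: str = "control",
    efficiency: float = 2.0,
    group_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-sample fold changes by the comparative-CT (ΔΔCT) method.

    ``control_label`` names the condition whose mean ΔCT is the baseline;
    the mean is taken per target gene (and per the optional ``group_cols``,
    e.g. per timepoint). Returns the input plus dct/ddct/fold_change columns.
    """
    _check_ct(table)
    out = table.copy()
    out["dct"] = out["ct_target"].astype(float) - out["ct_reference"].astype(float)
    keys = ["target_gene", *group_cols]

    def _per_group(g: pd.DataFrame) -> pd.DataFrame:
        ctrl = g.loc[g["condition"] == control_label, "dct"]
        if ctrl.empty:
            raise ValueError(
                f"no control sample ({control_label!r}) for target "
                f"{g['target_gene'].iloc[0]!r}"
            )
        g = g.copy()
        g["ddct"] = g["dct"] - ctrl.mean()     # arithmetic mean of control dCT
        return g

    out = (
        out.groupby(keys, group_keys=False, sort=False)[out.columns]
        .apply(_per_group)
        .reset_index(drop=True)
    )
    out["fold_change"] = efficiency ** (-out["ddct"])
    return out


def stability_index(fc_mature: float, fc_pre: float) -> float:
    """Mature-mRNA fold change relative to pre-mRNA fold change.

    1 means the expression change is explained by transcription alone; > 1
    means the mature transcript is stabilized beyond it.
    """
    fc_pre = float(fc_pre)
    if fc_pre <= 0:
        raise ValueError("pre-mRNA fold change must be positive")
    return float(fc_mature) / fc_pre


def validate_correlation(
    lnc_fc: pd.DataFrame,
    transcript_fc: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r and p between lncRNA and transcript qPCR fold changes.

    Both inputs are (feature x sample) fold-change matrices over matched
    samples; every (transcript, lncRNA) pair is correlated across the shared
    samples (>= 3 required).
    """
    shared = [s for s in transcript_fc.columns if s in set(lnc_fc.columns)]
    if len(shared) < 3:
        raise ValueError("need at least three paired observations")
    return _pearson_table(transcript_fc[shared], lnc_fc[shared]).rename(
        columns={"gene_id": "transcript", "lnc_id": "lnc"}
    )
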