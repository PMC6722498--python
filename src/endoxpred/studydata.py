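"""Accessors for the packaged published-cohort summary tables.

These are fixed published inputs (the 18-SNP verification panel with its
allele odds ratios and trend-test p-values, the ranked model traces, and
final model performance for the 287-patient cohort), not outputs of this
package; desk-scale checks re-derive arithmetic from them.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd


def verification_panel() -> pd.DataFrame:
    """The 18-variant verification panel (15 GWAS-selected + 3 CYP2D6)."""
    with resources.files("endoxpred.data").joinpath("verification_panel.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def reported_study() -> dict:
    """Published cohort counts, model traces and performance numbers."""
    text = resources.files("endoxpred.data").joinpath("reported_study.json").read_text()
    return json.loads(text)
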