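"""Bundled reference tables.

Currently one table: published CCS values for six SPLASH Lipidomix
standards measured on a cyclic-IMS instrument via the vendor single-pass
workflow and via single-pass / multipass perturbation-corrected
calibration, with the printed percent differences.  Used for arithmetic
cross-checks of :func:`cimscal.calibration.percent_difference` and the
single-/multipass consistency statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["splash_lipidomix_ccs", "consistency_stats"]


def splash_lipidomix_ccs() -> pd.DataFrame:
    """Published SPLASH Lipidomix CCS comparison table.

    Columns: ``standard``, ``adduct``, ``ccs_vendor`` (vendor single-pass
    workflow), ``ccs_single_pass`` / ``ccs_multipass`` (perturbation-
    corrected calibration) and the corresponding printed percent
    differences ``pdiff_single_pass`` / ``pdiff_multipass``.
    """
    with resources.files("cimscal.data").joinpath(
        "splash_lipidomix_ccs.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def consistency_stats(table: pd.DataFrame | None = None) -> dict[str, float]:
    """Agreement statistics across the lipid standards table.

    Returns the maximum relative difference (%) between the single-pass
    and multipass calibrated CCS columns, and the maximum printed percent
    difference against the vendor workflow.
    """
    if table is None:
        table = splash_lipidomix_ccs()
    sp = table["ccs_single_pass"]
    mp = table["ccs_multipass"]
    rel = (200.0 * (sp - mp).abs() / (sp + mp)).max()
    max_pdiff = float(
        pd.concat([table["pdiff_single_pass"], table["pdiff_multipass"]]).max()
    )
    return {
        "max_single_multi_rel_diff_pct": float(rel),
        "max_percent_difference_vs_vendor": max_pdiff,
    }
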