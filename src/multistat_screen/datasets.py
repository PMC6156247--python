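"""Packaged reference fixtures and default configurations.

Small plain-text resources shipped with the package: the top-25
IFNγ+LPS-induced gene fold-change table used as a worked example for the
FC-ratio inhibition criterion, and the default binding-site class
configuration with its synthetic PFMs (hand-built consensus-based stand-ins
for database matrices; see the individual .jaspar files).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .promoter_scan import PWMModel, SiteClassConfig, read_pfm

__all__ = ["load_top25_fold_changes", "load_default_site_classes"]

#: names of the three compounds whose inhibitor arms the fold-change table carries
TOP25_INHIBITORS = ("C01L_F03", "STATTIC", "STX-0119")


def load_top25_fold_changes() -> pd.DataFrame:
    """The 25 most strongly induced genes with their fold changes vs control.

    Columns: ``fc_stim`` (IFNγ+LPS vs untreated control, linear scale) and
    ``fc_<inhibitor>`` for each of the three compounds (IFNγ+LPS+inhibitor
    vs control).  Index: gene symbol.
    """
    ref = resources.files("multistat_screen").joinpath("data/top25_fold_changes.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="gene")


def load_default_site_classes(
    thresholds: dict[str, float] | None = None,
) -> tuple[list[SiteClassConfig], dict[str, PWMModel]]:
    """Default ISRE/GAS/NF-κB class configuration with packaged synthetic PFMs."""
    from .promoter_scan import DEFAULT_CLASS_THRESHOLDS

    thr = dict(DEFAULT_CLASS_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    files = {
        "ISRE": ["ISRE_synthetic.jaspar"],
        "GAS": ["GAS_synthetic.jaspar"],
        "NFKB": ["NFKB_synthetic.jaspar"],
    }
    classes: list[SiteClassConfig] = []
    pwms: dict[str, PWMModel] = {}
    for cls, names in files.items():
        ids = []
        for name in names:
            ref = resources.files("multistat_screen").joinpath(f"data/pfm/{name}")
            with resources.as_file(ref) as path:
                pwm = read_pfm(path)
            pwms[pwm.matrix_id] = pwm
            ids.append(pwm.matrix_id)
        classes.append(SiteClassConfig(class_id=cls, matrix_ids=ids, threshold=thr[cls]))
    return classes, pwms
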