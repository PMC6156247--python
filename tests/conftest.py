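"""Shared fixtures: small in-memory docking/expression/promoter objects."""

from __future__ import annotations

import numpy as np
import pytest

from multistat_screen.dock_model import PoseRecord
from multistat_screen.promoter_scan import pwm_from_counts


def make_pose(cid="C", tid="STAT1", rank=1, bs=5.0, crash=-1.0, polar=6.0,
              flags=(True, True), coords=None):
    return PoseRecord(
        compound_id=cid, target_id=tid, pose_rank=rank, bs=bs, crash=crash,
        polar_score=polar,
        flags=None if coords is not None else flags,
        coords=coords,
    )


def pose_set_with_classes(n_both=0, n_py0=0, n_pyx=0, n_neither=0,
                          cid="C", tid="STAT1"):
    """A ranked pose set with the given exclusive pocket-class counts."""
    flag_of = {"both": (True, True), "py0": (True, False),
               "pyx": (False, True), "neither": (False, False)}
    seq = (["both"] * n_both + ["py0"] * n_py0 + ["pyx"] * n_pyx
           + ["neither"] * n_neither)
    return [
        make_pose(cid=cid, tid=tid, rank=i + 1, bs=10.0 - 0.1 * i,
                  flags=flag_of[kind])
        for i, kind in enumerate(seq)
    ]


@pytest.fixture
def toy_pwm():
    """Sharp 4-column matrix with non-palindromic consensus ACGG."""
    counts = np.array([
        [90, 4, 3, 3],
        [3, 90, 4, 3],
        [3, 4, 90, 3],
        [3, 3, 90, 4],
    ], float)
    return pwm_from_counts("TOY.1", counts, pseudocount=1.0)


#: the twelve primary-screen binding scores of the purchased compounds
TABLE2_BS = {
    "A01": 7.56, "B01": 7.71, "C01": 8.09, "D01": 7.63, "E01": 8.36,
    "F01": 7.78, "G01": 7.81, "H01": 7.79, "I01": 7.76, "J01": 8.51,
    "K01": 7.58, "L01": 7.66,
}
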