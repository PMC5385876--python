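"""Published reference values from a nine-sample Danhong-injection study.

Danhong injection (DHI) is a two-herb preparation (Salvia miltiorrhiza +
Carthamus tinctorius) whose blood-circulation-promoting activity was
profiled over nine uniform-design formulation variants (S1-S9), thirteen
fingerprint components (P1-P13) and ten hemorheology/coagulation indices.
Two published result tables from that study are embedded here:

* the regression-method scores of the five varimax bioactivity factors
  over the nine samples, and
* the 5 x 13 grey relational degree (GRD) matrix between the factors and
  the components (rho = 0.5).

The underlying raw peak-area and per-animal pharmacology tables were
released only as supplementary material and are not redistributed; these
derived tables serve as regression anchors for the ranking and consensus
stages (e.g. the published per-factor top-3 component sets).
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["reference_factor_scores", "reference_grd_matrix"]

_FACTOR_SCORES = """\
sample,F1,F2,F3,F4,F5
S1,0.31,0.03,1.98,0.81,0.02
S2,0.37,1.77,0.18,-0.33,0.53
S3,1.17,0.76,0.13,-1.11,-0.94
S4,0.44,-0.07,-0.79,0.77,2.12
S5,1.37,-1.43,-1.01,-0.47,-0.42
S6,-0.54,-1.48,1.17,-0.36,0.24
S7,-0.34,0.21,-0.65,1.93,-1.44
S8,-1.15,0.08,-0.71,-0.07,0.04
S9,-1.62,0.13,-0.31,-1.15,-0.14
"""

_GRD = """\
factor,P1,P2,P3,P4,P5,P6,P7,P8,P9,P10,P11,P12,P13
F1,0.7524,0.6589,0.6222,0.7945,0.7217,0.6354,0.6174,0.6147,0.6547,0.6607,0.6325,0.6183,0.6411
F2,0.6370,0.6645,0.6260,0.5909,0.5818,0.6288,0.6281,0.6278,0.6197,0.6083,0.6406,0.6352,0.6117
F3,0.6499,0.7318,0.7162,0.6606,0.6686,0.7318,0.7193,0.7266,0.7266,0.7446,0.7178,0.7273,0.7252
F4,0.6412,0.6409,0.6544,0.6067,0.5841,0.6704,0.6569,0.6593,0.6428,0.6891,0.6269,0.6409,0.6291
F5,0.6387,0.6706,0.6738,0.6518,0.6837,0.6788,0.6860,0.6830,0.6831,0.6624,0.6804,0.6687,0.6879
"""


def reference_factor_scores() -> pd.DataFrame:
    """Published five-factor scores of the nine DHI formulation samples."""
    return pd.read_csv(io.StringIO(_FACTOR_SCORES), index_col="sample")


def reference_grd_matrix() -> pd.DataFrame:
    """Published factor x component grey relational degree matrix (rho = 0.5)."""
    return pd.read_csv(io.StringIO(_GRD), index_col="factor")
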