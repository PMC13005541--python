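"""Published group summary statistics for an elite-climber vs control cohort.

Per disc level (T1-T2 … L5-S1) and coarse AP subregion (1 anterior … 5
posterior): CSF-normalized T2 signal LS mean (SE) for each group, the
control − climber difference and its 95% confidence limits, from a
15 + 15 mixed-model analysis.  Values are used for internal-consistency
checks (the printed difference must agree with control − climber up to the
printed rounding) and to parameterize the default group-effect template of
the phantom generator, whose injected signal loss concentrates in the
nucleus bins (2–4) at the thoracolumbar junction.
"""

from __future__ import annotations

import io

import pandas as pd

_TABLE = """\
disc,subregion,climber_mean,climber_se,control_mean,control_se,diff,ci_low,ci_high
T1-T2,1,0.16,0.01,0.18,0.01,0.02,-0.02,0.05
T1-T2,2,0.21,0.02,0.24,0.01,0.03,-0.01,0.08
T1-T2,3,0.26,0.02,0.30,0.02,0.04,-0.01,0.09
T1-T2,4,0.23,0.02,0.27,0.02,0.05,-0.00,0.09
T1-T2,5,0.16,0.01,0.19,0.01,0.04,0.00,0.07
T2-T3,1,0.11,0.03,0.12,0.02,0.01,-0.15,0.17
T2-T3,2,0.22,0.02,0.25,0.02,0.03,-0.03,0.09
T2-T3,3,0.28,0.02,0.34,0.03,0.06,-0.02,0.14
T2-T3,4,0.31,0.02,0.39,0.04,0.09,-0.01,0.18
T2-T3,5,0.23,0.02,0.32,0.04,0.09,-0.01,0.20
T3-T4,1,0.13,0.01,0.17,0.01,0.03,0.01,0.06
T3-T4,2,0.22,0.01,0.25,0.01,0.03,-0.01,0.07
T3-T4,3,0.29,0.02,0.31,0.02,0.02,-0.03,0.08
T3-T4,4,0.28,0.02,0.30,0.02,0.02,-0.03,0.07
T3-T4,5,0.16,0.01,0.18,0.01,0.02,-0.02,0.05
T4-T5,1,0.12,0.01,0.13,0.01,0.01,-0.02,0.05
T4-T5,2,0.21,0.02,0.25,0.03,0.04,-0.03,0.11
T4-T5,3,0.32,0.02,0.34,0.03,0.03,-0.05,0.10
T4-T5,4,0.34,0.02,0.37,0.03,0.03,-0.04,0.11
T4-T5,5,0.22,0.02,0.25,0.02,0.02,-0.04,0.09
T5-T6,1,0.12,0.01,0.13,0.01,0.01,-0.02,0.04
T5-T6,2,0.17,0.01,0.19,0.01,0.02,-0.02,0.05
T5-T6,3,0.28,0.02,0.30,0.02,0.02,-0.05,0.09
T5-T6,4,0.31,0.02,0.31,0.02,-0.01,-0.07,0.06
T5-T6,5,0.19,0.02,0.20,0.02,0.01,-0.04,0.06
T6-T7,1,0.10,0.01,0.11,0.01,0.01,-0.01,0.03
T6-T7,2,0.16,0.01,0.20,0.02,0.05,-0.00,0.10
T6-T7,3,0.28,0.02,0.31,0.03,0.03,-0.04,0.10
T6-T7,4,0.32,0.03,0.31,0.02,-0.01,-0.08,0.06
T6-T7,5,0.21,0.02,0.22,0.02,0.01,-0.05,0.07
T7-T8,1,0.10,0.01,0.12,0.01,0.02,0.00,0.04
T7-T8,2,0.16,0.01,0.21,0.02,0.05,0.00,0.09
T7-T8,3,0.31,0.03,0.35,0.02,0.04,-0.03,0.11
T7-T8,4,0.33,0.02,0.36,0.03,0.04,-0.03,0.11
T7-T8,5,0.21,0.02,0.23,0.02,0.02,-0.03,0.07
T8-T9,1,0.10,0.01,0.11,0.01,0.01,-0.01,0.03
T8-T9,2,0.19,0.03,0.25,0.04,0.05,-0.04,0.15
T8-T9,3,0.35,0.03,0.38,0.04,0.03,-0.06,0.12
T8-T9,4,0.36,0.02,0.40,0.03,0.04,-0.04,0.12
T8-T9,5,0.20,0.02,0.23,0.02,0.03,-0.02,0.08
T9-T10,1,0.10,0.01,0.12,0.01,0.03,0.01,0.04
T9-T10,2,0.19,0.02,0.25,0.02,0.06,-0.00,0.12
T9-T10,3,0.35,0.03,0.41,0.03,0.06,-0.02,0.14
T9-T10,4,0.38,0.03,0.42,0.04,0.04,-0.05,0.13
T9-T10,5,0.19,0.01,0.23,0.02,0.04,-0.01,0.09
T10-T11,1,0.10,0.01,0.13,0.01,0.03,0.00,0.06
T10-T11,2,0.22,0.02,0.33,0.03,0.11,0.03,0.18
T10-T11,3,0.37,0.02,0.48,0.03,0.11,0.03,0.19
T10-T11,4,0.41,0.02,0.46,0.03,0.06,-0.02,0.13
T10-T11,5,0.21,0.02,0.24,0.02,0.03,-0.03,0.09
T11-T12,1,0.11,0.01,0.17,0.03,0.07,-0.01,0.14
T11-T12,2,0.23,0.02,0.39,0.05,0.16,0.04,0.28
T11-T12,3,0.37,0.03,0.54,0.05,0.17,0.05,0.29
T11-T12,4,0.42,0.02,0.52,0.04,0.10,0.02,0.19
T11-T12,5,0.18,0.01,0.22,0.02,0.04,-0.01,0.09
T12-L1,1,0.09,0.01,0.13,0.02,0.04,0.01,0.08
T12-L1,2,0.23,0.01,0.33,0.02,0.10,0.04,0.16
T12-L1,3,0.35,0.02,0.46,0.03,0.12,0.04,0.19
T12-L1,4,0.41,0.02,0.51,0.02,0.10,0.04,0.16
T12-L1,5,0.20,0.02,0.25,0.03,0.05,-0.02,0.12
L1-L2,1,0.09,0.01,0.12,0.01,0.04,0.02,0.05
L1-L2,2,0.19,0.01,0.31,0.02,0.12,0.07,0.16
L1-L2,3,0.31,0.02,0.44,0.02,0.13,0.06,0.19
L1-L2,4,0.36,0.02,0.47,0.02,0.12,0.05,0.19
L1-L2,5,0.15,0.01,0.19,0.01,0.05,0.01,0.08
L2-L3,1,0.10,0.01,0.13,0.01,0.03,0.01,0.05
L2-L3,2,0.27,0.02,0.37,0.02,0.10,0.04,0.16
L2-L3,3,0.43,0.02,0.52,0.03,0.09,0.01,0.18
L2-L3,4,0.44,0.02,0.54,0.03,0.10,0.03,0.17
L2-L3,5,0.18,0.01,0.22,0.01,0.04,0.01,0.08
L3-L4,1,0.09,0.00,0.13,0.01,0.04,0.02,0.06
L3-L4,2,0.26,0.02,0.36,0.03,0.10,0.03,0.17
L3-L4,3,0.38,0.02,0.49,0.03,0.11,0.04,0.18
L3-L4,4,0.31,0.02,0.42,0.03,0.12,0.04,0.19
L3-L4,5,0.11,0.01,0.14,0.01,0.03,0.01,0.05
L4-L5,1,0.10,0.01,0.14,0.01,0.04,0.02,0.06
L4-L5,2,0.29,0.02,0.30,0.03,0.01,-0.06,0.08
L4-L5,3,0.39,0.02,0.38,0.04,-0.00,-0.09,0.08
L4-L5,4,0.29,0.02,0.31,0.03,0.01,-0.06,0.09
L4-L5,5,0.12,0.01,0.13,0.01,0.01,-0.01,0.03
L5-S1,1,0.09,0.01,0.12,0.01,0.03,0.01,0.05
L5-S1,2,0.21,0.02,0.28,0.03,0.07,-0.00,0.14
L5-S1,3,0.27,0.02,0.34,0.04,0.07,-0.02,0.15
L5-S1,4,0.19,0.01,0.26,0.03,0.07,0.00,0.13
L5-S1,5,0.09,0.00,0.10,0.00,0.01,-0.00,0.02
"""

#: Discs over which the reference effect concentrates (thoracolumbar
#: junction through mid-lumbar), used for the default injected template.
EFFECT_DISCS = ("T10-T11", "T11-T12", "T12-L1", "L1-L2", "L2-L3", "L3-L4")
NUCLEUS_BINS = (2, 3, 4)


def reference_contrasts() -> pd.DataFrame:
    """The reference per-disc × subregion contrast table as a DataFrame."""
    df = pd.read_csv(io.StringIO(_TABLE))
    df["significant"] = (df["ci_low"] > 0) | (df["ci_high"] < 0)
    return df


def default_group_effect() -> dict[str, dict[int, float]]:
    """Injected control − climber signal loss per (disc, coarse bin).

    The reference differences at nucleus bins 2–4 of the thoracolumbar
    discs; annulus bins (1 and 5) carry no injected effect.
    """
    df = reference_contrasts()
    out: dict[str, dict[int, float]] = {}
    for disc in EFFECT_DISCS:
        sub = df[(df["disc"] == disc) & df["subregion"].isin(NUCLEUS_BINS)]
        out[disc] = {int(r.subregion): float(r.diff) for r in sub.itertuples(index=False)}
    return out
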