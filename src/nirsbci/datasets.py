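"""Bundled reference tables.

``load_benchmark_accuracies`` returns the published subject-wise LOOCV
classification accuracies (percent) of a 29-subject motor-imagery /
mental-arithmetic fNIRS-BCI benchmark, for three channel-selection arms
(z-score method, t-value method, all channels) and three tasks (MA, LMI,
RMI). The table serves as the reference input for the method-comparison
statistics: column means and paired tests are recomputed from it rather
than asserted.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["load_benchmark_accuracies", "BENCHMARK_TASKS", "BENCHMARK_METHODS"]

BENCHMARK_TASKS = ("MA", "LMI", "RMI")
BENCHMARK_METHODS = ("zscore", "tvalue", "all")

# columns: <task>_<method>; one row per subject; accuracies in percent
_TABLE = """\
subject,MA_zscore,MA_tvalue,MA_all,LMI_zscore,LMI_tvalue,LMI_all,RMI_zscore,RMI_tvalue,RMI_all
1,75,85,90,90,70,55,90,70,75
2,90,70,80,85,80,90,85,65,75
3,80,70,70,95,75,65,90,80,75
4,95,80,80,85,70,75,85,80,65
5,90,65,55,90,55,80,85,75,65
6,90,45,55,95,80,85,90,60,65
7,90,70,80,80,65,65,90,55,85
8,90,60,90,90,80,85,85,85,85
9,90,80,60,75,65,70,100,90,85
10,85,80,85,80,70,75,85,80,70
11,95,90,85,85,70,70,95,70,70
12,90,75,75,95,80,80,75,65,65
13,95,45,70,90,70,70,90,90,80
14,90,70,70,95,85,90,95,65,65
15,95,70,75,85,85,85,90,75,90
16,75,75,70,90,80,75,90,60,80
17,85,80,80,95,80,85,95,80,85
18,85,90,90,90,70,85,90,90,90
19,85,80,85,70,85,85,80,85,80
20,95,95,85,95,50,80,95,60,60
21,75,80,80,85,75,80,85,60,90
22,85,75,85,80,60,70,95,80,75
23,80,75,80,95,80,80,80,65,70
24,95,60,80,80,70,85,90,35,75
25,100,90,80,95,85,90,75,45,50
26,90,85,90,80,80,70,95,70,75
27,80,65,75,85,75,65,95,85,85
28,100,60,70,95,85,85,90,75,90
29,85,80,80,80,85,80,80,45,55
"""


def load_benchmark_accuracies() -> pd.DataFrame:
    """Published 29-subject benchmark accuracies, one row per subject.

    Columns are ``<task>_<method>`` for tasks MA/LMI/RMI and methods
    zscore/tvalue/all, values in percent.
    """
    return pd.read_csv(StringIO(_TABLE), index_col="subject")
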