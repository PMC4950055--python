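"""Published Down syndrome birth-weight reference for England and Wales.

The built-in chart below is the published LMS reference for birth weight in
live-born babies with free trisomy 21 in England and Wales (national
cytogenetic register births, 1989-2011; n = 8,825): per completed week of
gestation from 28 to 43, the number of boys and girls and the fitted LMS
parameters.  The skewness L and coefficient of variation S are shared by
sex; the girls' median runs a constant 2.4% below the boys' (log-link
constant sex offset).

These values serve two roles: the default generating truth for the
synthetic register simulator, and the worked-example chart for centile
tabulation.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .bccg import LMSTable

__all__ = ["reference_counts", "reference_lms_table", "REFERENCE_TOTAL"]

# week, boys n, girls n, boys M (g), girls M (g), L, S
_REFERENCE = """\
week	n_M	n_F	M_M	M_F	L	S
28	11	10	960	937	-0.12	0.266
29	16	19	1132	1105	-0.03	0.253
30	26	23	1319	1288	0.06	0.243
31	29	27	1518	1482	0.15	0.237
32	73	41	1719	1678	0.23	0.233
33	84	54	1915	1869	0.31	0.228
34	117	85	2113	2063	0.39	0.220
35	192	156	2333	2277	0.47	0.206
36	414	298	2567	2506	0.55	0.189
37	693	525	2800	2733	0.62	0.174
38	1219	921	3019	2947	0.69	0.162
39	822	824	3164	3088	0.76	0.153
40	797	809	3251	3174	0.83	0.150
41	204	207	3304	3225	0.89	0.151
42	55	56	3318	3239	0.96	0.152
43	8	10	3300	3221	1.02	0.153
"""

REFERENCE_TOTAL = 8825


def _wide() -> pd.DataFrame:
    return pd.read_csv(StringIO(_REFERENCE), sep="\t")


def reference_counts() -> pd.DataFrame:
    """Births per (sex, week) in the reference register.

    Returns a long DataFrame with columns ``sex`` ("M"/"F"), ``week`` and
    ``n``; the counts sum to 8,825 (4,760 boys, 4,065 girls) and peak at the
    modal gestation of 38 weeks.
    """
    w = _wide()
    rows = []
    for _, r in w.iterrows():
        rows.append({"sex": "M", "week": int(r["week"]), "n": int(r["n_M"])})
        rows.append({"sex": "F", "week": int(r["week"]), "n": int(r["n_F"])})
    return pd.DataFrame(rows)


def reference_lms_table() -> LMSTable:
    """The reference LMS chart for both sexes, weeks 28-43."""
    w = _wide()
    rows = []
    for _, r in w.iterrows():
        rows.append(
            {"sex": "M", "week": int(r["week"]), "L": r["L"], "M": r["M_M"], "S": r["S"]}
        )
        rows.append(
            {"sex": "F", "week": int(r["week"]), "L": r["L"], "M": r["M_F"], "S": r["S"]}
        )
    return LMSTable(pd.DataFrame(rows))
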