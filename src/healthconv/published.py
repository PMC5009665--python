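"""Published reference estimates from the EU-27 regional study (1995-2011).

Posterior mean (sd) pairs of the fixed effects and of the significant
country/year deviations of the lag coefficient, for the five health
outcomes, as printed by the source study of EU regional health-inequality
convergence.  Stars mark coefficients whose 95% credible interval excluded
zero.  These serve as fixtures for the summary-mode significance
classifier: feeding each (mean, sd) pair through the mean +/- 1.96 sd rule
must reproduce every printed marker and every verbal above/below-average
label.
"""

from __future__ import annotations

OUTCOMES = (
    "life_expectancy", "total_mortality", "ischemic", "cancer", "lung_cancer",
)

#: fixed-effect rows: name -> {outcome: (mean, sd, starred)}
FIXED_EFFECTS: dict[str, dict[str, tuple[float, float, bool]]] = {
    "intercept": {
        "life_expectancy": (2.2631, 0.0820, True),
        "total_mortality": (3.6644, 0.3307, True),
        "ischemic": (1.3910, 0.3605, True),
        "cancer": (4.3019, 0.3285, True),
        "lung_cancer": (1.0064, 0.3070, True),
    },
    "beta_lag_outcome": {
        "life_expectancy": (-0.5109, 0.0188, True),
        "total_mortality": (-0.5258, 0.0468, True),
        "ischemic": (-0.2751, 0.0336, True),
        "cancer": (-0.9980, 0.0345, True),
        "lung_cancer": (-0.5075, 0.0410, True),
    },
    "log_gdppc": {
        "life_expectancy": (0.0000, 0.0001, False),
        "total_mortality": (0.0041, 0.0008, True),
        "ischemic": (0.0025, 0.0036, False),
        "cancer": (0.0008, 0.0018, False),
        "lung_cancer": (0.0005, 0.020, False),
    },
    "log_gdppc_lag1": {
        "life_expectancy": (0.000, 0.0001, False),
        "total_mortality": (-0.0044, 0.0010, True),
        "ischemic": (-0.0038, 0.0042, False),
        "cancer": (-0.0039, 0.0022, False),
        "lung_cancer": (-0.0022, 0.0024, False),
    },
    "log_gdppc_lag2": {
        "life_expectancy": (-0.0001, 0.0001, False),
        "total_mortality": (0.0003, 0.0007, False),
        "ischemic": (-0.0056, 0.0055, False),
        "cancer": (-0.0039, 0.0035, False),
        "lung_cancer": (0.0109, 0.0032, True),
    },
    "log_gini": {
        "life_expectancy": (-0.1836, 0.0592, True),
        "total_mortality": (-1.0516, 0.5612, False),
        "ischemic": (2.0101, 1.3376, False),
        "cancer": (0.5313, 0.7758, False),
        "lung_cancer": (1.8337, 0.8369, True),
    },
    "log_gini_lag1": {
        "life_expectancy": (0.0280, 0.0274, False),
        "total_mortality": (1.0406, 0.5213, True),
        "ischemic": (-1.72, 1.1931, False),
        "cancer": (2.2466, 0.6853, True),
        "lung_cancer": (-0.0302, 0.7540, False),
    },
    "log_empht": {
        "life_expectancy": (0.001, 0.000, True),
        "total_mortality": (0.0001, 0.0005, False),
        "ischemic": (0.0038, 0.0019, True),
        "cancer": (-0.0027, 0.0014, False),
        "lung_cancer": (-0.0019, 0.0015, False),
    },
    "log_univ": {
        "life_expectancy": (-0.0023, 0.0013, False),
        "total_mortality": (-0.0023, 0.0130, False),
        "ischemic": (0.1488, 0.0587, True),
        "cancer": (0.1074, 0.0318, True),
        "lung_cancer": (0.1181, 0.0363, True),
    },
    "log_umy": {
        "life_expectancy": (0.0013, 0.0017, False),
        "total_mortality": (-0.0313, 0.0167, False),
        "ischemic": (0.1876, 0.0657, True),
        "cancer": (-0.0219, 0.0363, False),
        "lung_cancer": (0.1075, 0.0402, True),
    },
    "log_ufy": {
        "life_expectancy": (0.0002, 0.0014, False),
        "total_mortality": (0.0108, 0.0134, False),
        "ischemic": (-0.2707, 0.0524, True),
        "cancer": (-0.1870, 0.0281, True),
        "lung_cancer": (-0.2125, 0.0320, True),
    },
    "log_randd": {
        "life_expectancy": (0.0078, 0.0091, False),
        "total_mortality": (-0.0475, 0.0960, False),
        "ischemic": (0.4954, 0.3590, False),
        "cancer": (0.0083, 0.1893, False),
        "lung_cancer": (-0.0288, 0.2127, False),
    },
    "bpg": {
        "life_expectancy": (0.0237, 0.0038, True),
        "total_mortality": (0.07, 0.0363, False),
        "ischemic": (-0.1082, 0.1749, False),
        "cancer": (-0.1175, 0.1052, False),
        "lung_cancer": (0.0981, 0.1178, False),
    },
    "log_pubexp": {
        "life_expectancy": (0.0081, 0.0039, True),
        "total_mortality": (-0.2011, 0.0427, True),
        "ischemic": (-0.3496, 0.1734, True),
        "cancer": (0.1256, 0.0931, False),
        "lung_cancer": (0.1642, 0.1095, False),
    },
    "d2004": {
        "life_expectancy": (0.0051, 0.0025, True),
        "total_mortality": (-0.0332, 0.0138, True),
        "ischemic": (-0.0107, 0.1082, False),
        "cancer": (-0.0102, 0.0808, False),
        "lung_cancer": (-0.0042, 0.0475, False),
    },
    "d2007": {
        "life_expectancy": (0.0006, 0.0025, False),
        "total_mortality": (-0.0132, 0.0139, False),
        "ischemic": (-0.0284, 0.1083, False),
        "cancer": (-0.0158, 0.0808, False),
        "lung_cancer": (-0.0121, 0.0476, False),
    },
    "d2008": {
        "life_expectancy": (0.0011, 0.0025, False),
        "total_mortality": (0.0286, 0.0139, True),
        "ischemic": (-0.0257, 0.1083, False),
        "cancer": (0.0103, 0.0809, False),
        "lung_cancer": (0.0148, 0.0476, False),
    },
}

#: significant country deviations of the lag coefficient: outcome ->
#: {country: (mean, sd)}; all printed entries are starred by construction
COUNTRY_DEVIATIONS: dict[str, dict[str, tuple[float, float]]] = {
    "life_expectancy": {
        "Estonia": (-0.066, 0.025), "Greece": (0.045, 0.014),
        "Hungary": (-0.031, 0.015), "Italy": (0.027, 0.012),
        "Poland": (-0.026, 0.011), "Portugal": (-0.045, 0.015),
        "Spain": (0.032, 0.012), "Sweden": (0.038, 0.017),
    },
    "total_mortality": {
        "Ireland": (-0.454, 0.102), "Poland": (1.213, 0.089),
    },
    "ischemic": {
        "Czech Republic": (0.3096, 0.087), "France": (-0.1286, 0.0493),
        "Netherlands": (-0.1132, 0.0479),
    },
    "cancer": {
        "Bulgaria": (0.1765, 0.0816), "Czech Republic": (0.5614, 0.0909),
        "Hungary": (0.1596, 0.082),
    },
    "lung_cancer": {
        "Czech Republic": (0.2767, 0.0812), "Germany": (-0.1319, 0.053),
        "Hungary": (0.261, 0.1011),
    },
}

#: significant year deviations of the lag coefficient: outcome -> {year: (mean, sd)}
YEAR_DEVIATIONS: dict[str, dict[int, tuple[float, float]]] = {
    "life_expectancy": {
        1996: (-0.007, 0.002), 1997: (-0.006, 0.002),
        1998: (-0.005, 0.002), 2011: (-0.009, 0.004),
    },
    "total_mortality": {2000: (-0.029, 0.013), 2005: (0.037, 0.014)},
    "ischemic": {2010: (0.4154, 0.1870)},
    "cancer": {2010: (0.3011, 0.1392)},
    "lung_cancer": {2010: (0.1778, 0.0827)},
}

#: verbal convergence-rate labels stated in the study's results narrative
EXPECTED_COUNTRY_LABELS: dict[str, dict[str, str]] = {
    "life_expectancy": {
        "Estonia": "below_average", "Portugal": "below_average",
        "Poland": "below_average", "Hungary": "below_average",
        "Greece": "above_average", "Sweden": "above_average",
        "Spain": "above_average", "Italy": "above_average",
    },
    "total_mortality": {"Ireland": "below_average", "Poland": "above_average"},
    "ischemic": {
        "France": "below_average", "Netherlands": "below_average",
        "Czech Republic": "above_average",
    },
    "cancer": {
        "Czech Republic": "above_average", "Hungary": "above_average",
        "Bulgaria": "above_average",
    },
    "lung_cancer": {
        "Germany": "below_average", "Czech Republic": "above_average",
        "Hungary": "above_average",
    },
}

#: outcomes for which a 2010 divergence (positive significant year
#: deviation) is reported
DIVERGENCE_2010_OUTCOMES = ("ischemic", "cancer", "lung_cancer")

#: printed (mean, sd) pairs whose |mean|/sd falls between 1.9 and 1.96:
#: flagged significant by the source's posterior-quantile criterion but not
#: reproducible by the mean +/- 1.96 sd normal approximation at the printed
#: precision
BORDERLINE_PAIRS = {("cancer", "Hungary")}
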