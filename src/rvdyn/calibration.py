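"""Default group-level calibration for the synthetic cohorts.

Means and standard deviations of the endocardial and paced-ECG parameters
for the four study groups (normal hearts, benign RVOT ectopy, definite ARVC
and probable ARVC), taken from a published clinical high-density-mapping
study of early ARVC.  They parameterise the cohort generator so that
synthetic cohorts reproduce the printed group statistics; they are *not*
fitted by this package.

All times are ms.  ``mid`` (mean increase in delay) is given as the printed
median and interquartile range and is modelled lognormal; when the printed
lower quartile is 0 the log-scale spread is fitted from the median-to-upper-
quartile ratio instead of the IQR ratio.

``frac_*`` entries are mean deflection counts (dimensionless, truncated at
1 deflection).  ``ecg_steady`` holds the five paced-ECG landmark means
(latency, QRS peak, J-point, T peak, T end, from the stimulus);
``ecg_hysteresis`` holds the pre-ERP-minus-steady change of the five
stimulus-to-landmark intervals.
"""

from __future__ import annotations

import math

# (mean, sd) unless noted; truncation bounds applied by the generator.
GROUP_DEFAULTS: dict[str, dict] = {
    "normal": {
        "verp": (212.0, 23.0),
        "at_ss": (79.0, 29.0),
        "ari_ss": (194.0, 25.0),
        "delta_at_preverp": (26.0, 16.0),
        "delta_rt_preverp": (-7.0, 22.0),
        "frac_ss": (2.5, 0.6),
        "frac_preverp": (2.4, 0.5),
        "frac_sinus": (3.0, 1.4),
        "sinus_at_span": (71.0, 19.0),
        "sinus_rt": (302.0, 44.0),
        "sinus_ari": (230.0, 49.0),
        "mid": {"median": 3.4, "iqr": (0.0, 5.2)},
        "ecg_steady": {"latency": (37.0, 10.0), "qrs_peak": (85.0, 13.0),
                       "j_point": (147.0, 18.0), "t_peak": (269.0, 21.0),
                       "t_end": (351.0, 28.0)},
        "ecg_hysteresis": {"latency": (24.0, 9.0), "qrs_peak": (30.0, 19.0),
                           "j_point": (24.0, 24.0), "t_peak": (-5.0, 25.0),
                           "t_end": (17.0, 22.0)},
    },
    "rvot_ectopy": {
        "verp": (210.0, 13.0),
        "at_ss": (58.0, 24.0),
        "ari_ss": (201.0, 20.0),
        "delta_at_preverp": (34.0, 14.0),
        "delta_rt_preverp": (-2.0, 22.0),
        "frac_ss": (3.4, 0.9),
        "frac_preverp": (3.4, 1.1),
        "frac_sinus": (3.44, 1.66),
        "sinus_at_span": (76.0, 25.0),
        "sinus_rt": (311.0, 49.0),
        "sinus_ari": (235.0, 44.0),
        "mid": {"median": 4.3, "iqr": (1.4, 7.1)},
        "ecg_steady": {"latency": (42.0, 13.0), "qrs_peak": (90.0, 11.0),
                       "j_point": (149.0, 22.0), "t_peak": (270.0, 24.0),
                       "t_end": (342.0, 26.0)},
        "ecg_hysteresis": {"latency": (24.0, 8.0), "qrs_peak": (38.0, 15.0),
                           "j_point": (32.0, 19.0), "t_peak": (-5.0, 15.0),
                           "t_end": (17.0, 22.0)},
    },
    "definite_arvc": {
        "verp": (205.0, 16.0),
        "at_ss": (75.0, 22.0),
        "ari_ss": (203.0, 23.0),
        "delta_at_preverp": (48.0, 21.0),
        "delta_rt_preverp": (15.0, 29.0),
        "frac_ss": (3.1, 1.1),
        "frac_preverp": (3.0, 1.0),
        "frac_sinus": (2.84, 1.31),
        "sinus_at_span": (81.0, 19.0),
        "sinus_rt": (320.0, 40.0),
        "sinus_ari": (239.0, 38.0),
        "mid": {"median": 7.0, "iqr": (3.6, 9.3)},
        "ecg_steady": {"latency": (34.0, 9.0), "qrs_peak": (81.0, 19.0),
                       "j_point": (142.0, 32.0), "t_peak": (269.0, 24.0),
                       "t_end": (347.0, 20.0)},
        "ecg_hysteresis": {"latency": (32.0, 12.0), "qrs_peak": (47.0, 13.0),
                           "j_point": (50.0, 12.0), "t_peak": (1.0, 19.0),
                           "t_end": (35.0, 23.0)},
    },
    "probable_arvc": {
        "verp": (214.0, 18.0),
        "at_ss": (79.0, 28.0),
        "ari_ss": (204.0, 19.0),
        "delta_at_preverp": (38.0, 21.0),
        "delta_rt_preverp": (1.0, 29.0),
        "frac_ss": (3.3, 1.0),
        "frac_preverp": (3.1, 1.1),
        "frac_sinus": (2.91, 1.1),
        "sinus_at_span": (80.0, 19.0),
        "sinus_rt": (317.0, 42.0),
        "sinus_ari": (237.0, 38.0),
        "mid": {"median": 6.3, "iqr": (3.3, 9.5)},
        "ecg_steady": {"latency": (39.0, 11.0), "qrs_peak": (95.0, 15.0),
                       "j_point": (159.0, 9.0), "t_peak": (268.0, 40.0),
                       "t_end": (361.0, 17.0)},
        "ecg_hysteresis": {"latency": (27.0, 12.0), "qrs_peak": (40.0, 13.0),
                           "j_point": (33.0, 17.0), "t_peak": (-4.0, 31.0),
                           "t_end": (14.0, 21.0)},
    },
}

# Fraction of each parameter's variance attributed to between-patient
# differences; the remainder is per-electrode scatter within a patient.
BETWEEN_PATIENT_VARIANCE_FRACTION = 0.7


def lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of a lognormal solved from a printed median and IQR.

    sigma is taken from the quartile *ratio* (the printed quartiles are not
    generally symmetric about the median on the log scale, so no lognormal
    matches all three numbers exactly; the median is honoured exactly).
    A lower quartile of 0 falls back to the median-to-Q3 ratio.
    """
    if median <= 0:
        raise ValueError("lognormal median must be positive")
    q1, q3 = iqr
    if q1 > 0:
        sigma = math.log(q3 / q1) / (2 * 0.6744897501960817)
    else:
        sigma = math.log(q3 / median) / 0.6744897501960817
    return math.log(median), sigma
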