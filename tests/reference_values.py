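"""Published summary values from the Nanning rice surveillance study.

These are the printed anchors the package is checked against: the
deterministic dose/THQ block, the rice-vs-paddy exceedance counts with
their chi-square statistics, the overall detection/exceedance counts, the
stratified monthly-intake (EMI) tables at the P50 and P75 exposure levels,
and the fitted Monte Carlo input distributions.
"""

# --- deterministic block: element -> (ADD mg/(kg*day), RfD mg/(kg*day), printed THQ)
DETERMINISTIC_THQ = {
    "Cd": (0.000449, 0.0005, 0.898),
    "Pb": (0.000146, 0.0014, 0.104),
    "Hg": (0.0000273, 0.0003, 0.091),
    "iAs": (0.0000108, 0.0003, 0.036),
}
HI_PRINTED = 1.13

# --- carcinogenic block (printed CRs; the Pb CR is not arithmetically
#     consistent with its printed ADD and is anchored only through the CCR)
CR_PRINTED = {"Pb": 1.24e-6, "iAs": 1.63e-5}
CCR_PRINTED = 1.75e-5

# --- rice vs paddy 2x2 comparisons: element -> (paddy_exceed, paddy_n,
#     rice_exceed, rice_n, printed chi2)
CHI2_TABLE = {
    "Pb": (3, 180, 8, 358, 0.19),
    "Cd": (24, 180, 64, 358, 1.81),
    "iAs": (32, 180, 2, 358, 59.99),
    "Hg": (4, 180, 3, 358, 1.79),
    "Total": (60, 180, 75, 358, 9.77),
}

# --- overall surveillance counts (2019-2020, n = 538 per element)
DETECTION_COUNTS = {  # element -> (n, detected, printed rate %)
    "Pb": (538, 290, 53.90),
    "Cd": (538, 533, 99.07),
    "iAs": (538, 134, 24.91),
    "Hg": (538, 537, 99.81),
}
EXCEEDANCE_COUNTS = {  # element -> (n, exceeded, printed rate %)
    "Pb": (538, 11, 2.04),
    "Cd": (538, 88, 16.36),
    "iAs": (538, 34, 6.32),
    "Hg": (538, 7, 1.30),
}

# --- stratified cadmium EMI/THQ tables (ug/kg BW/month vs PTMI = 25).
#     Rows: (exposure level, district, age group, sex, printed EMI, printed THQ).
EMI_THQ_CELLS = [
    ("P50", "Mashan", "6-17", "male", 14.43, 0.58),
    ("P50", "Mashan", "6-17", "female", 13.45, 0.54),
    ("P50", "Mashan", ">=18", "male", 11.57, 0.46),
    ("P50", "Mashan", ">=18", "female", 10.81, 0.43),
    ("P50", "Long'an", "6-17", "male", 14.09, 0.56),
    ("P50", "Long'an", "6-17", "female", 13.13, 0.53),
    ("P50", "Long'an", ">=18", "male", 11.31, 0.45),
    ("P50", "Long'an", ">=18", "female", 10.56, 0.42),
    ("P50", "Hengxian", "6-17", "male", 21.81, 0.87),
    ("P50", "Hengxian", "6-17", "female", 20.32, 0.81),
    ("P50", "Hengxian", ">=18", "male", 17.5, 0.7),
    ("P50", "Hengxian", ">=18", "female", 16.34, 0.65),
    ("P50", "Shanglin", "6-17", "male", 16.94, 0.68),
    ("P50", "Shanglin", "6-17", "female", 15.79, 0.63),
    ("P50", "Shanglin", ">=18", "male", 13.59, 0.54),
    ("P50", "Shanglin", ">=18", "female", 12.69, 0.51),
    ("P50", "Wuming", "6-17", "male", 29.35, 1.17),
    ("P50", "Wuming", "6-17", "female", 27.36, 1.09),
    ("P50", "Wuming", ">=18", "male", 23.55, 0.94),
    ("P50", "Wuming", ">=18", "female", 21.99, 0.88),
    ("P50", "Jiangnan", "6-17", "male", 13.75, 0.55),
    ("P50", "Jiangnan", "6-17", "female", 12.82, 0.51),
    ("P50", "Jiangnan", ">=18", "male", 11.04, 0.44),
    ("P50", "Jiangnan", ">=18", "female", 10.3, 0.41),
    ("P50", "Binyang", "6-17", "male", 18.28, 0.73),
    ("P50", "Binyang", "6-17", "female", 17.04, 0.68),
    ("P50", "Binyang", ">=18", "male", 14.67, 0.59),
    ("P50", "Binyang", ">=18", "female", 13.7, 0.55),
    ("P50", "Nanning Suburban", "6-17", "male", 10.23, 0.41),
    ("P50", "Nanning Suburban", "6-17", "female", 9.54, 0.38),
    ("P50", "Nanning Suburban", ">=18", "male", 8.21, 0.33),
    ("P50", "Nanning Suburban", ">=18", "female", 7.67, 0.31),
    ("P75", "Mashan", "6-17", "male", 46.97, 1.88),
    ("P75", "Mashan", "6-17", "female", 43.77, 1.75),
    ("P75", "Mashan", ">=18", "male", 37.68, 1.51),
    ("P75", "Mashan", ">=18", "female", 35.18, 1.41),
    ("P75", "Long'an", "6-17", "male", 28.52, 1.14),
    ("P75", "Long'an", "6-17", "female", 26.58, 1.06),
    ("P75", "Long'an", ">=18", "male", 22.88, 0.92),
    ("P75", "Long'an", ">=18", "female", 21.36, 0.85),
    ("P75", "Hengxian", "6-17", "male", 33.55, 1.34),
    ("P75", "Hengxian", "6-17", "female", 31.27, 1.25),
    ("P75", "Hengxian", ">=18", "male", 26.92, 1.08),
    ("P75", "Hengxian", ">=18", "female", 25.13, 1.01),
    ("P75", "Shanglin", "6-17", "male", 33.21, 1.33),
    ("P75", "Shanglin", "6-17", "female", 30.95, 1.24),
    ("P75", "Shanglin", ">=18", "male", 26.65, 1.07),
    ("P75", "Shanglin", ">=18", "female", 24.88, 1.0),
    ("P75", "Wuming", "6-17", "male", 68.94, 2.76),
    ("P75", "Wuming", "6-17", "female", 64.25, 2.57),
    ("P75", "Wuming", ">=18", "male", 55.31, 2.21),
    ("P75", "Wuming", ">=18", "female", 51.65, 2.07),
    ("P75", "Jiangnan", "6-17", "male", 13.75, 0.55),
    ("P75", "Jiangnan", "6-17", "female", 12.82, 0.51),
    ("P75", "Jiangnan", ">=18", "male", 11.04, 0.44),
    ("P75", "Jiangnan", ">=18", "female", 10.3, 0.41),
    ("P75", "Binyang", "6-17", "male", 31.2, 1.25),
    ("P75", "Binyang", "6-17", "female", 29.08, 1.16),
    ("P75", "Binyang", ">=18", "male", 25.03, 1.0),
    ("P75", "Binyang", ">=18", "female", 23.37, 0.93),
    ("P75", "Nanning Suburban", "6-17", "male", 20.3, 0.81),
    ("P75", "Nanning Suburban", "6-17", "female", 18.92, 0.76),
    ("P75", "Nanning Suburban", ">=18", "male", 16.28, 0.65),
    ("P75", "Nanning Suburban", ">=18", "female", 15.2, 0.61),
]
PTMI_CD = 25.0

# --- Monte Carlo input distributions and published outputs
CD_LOGNORMAL = {"m": 0.16781, "s": 0.27126, "tau": -0.0015274}
INTAKE_TRIANGULAR = {"a": 121.63, "c": 231.56, "b": 308.42}
MC_BW = 60.0
MC_RFD = 0.001
MC_ITERATIONS = 5000
MC_MEAN_THQ = 0.610
MC_P_THQ_GE_1 = 0.158
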