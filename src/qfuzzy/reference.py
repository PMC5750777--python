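"""Published reference scores for Q-Fuzzy-style selection on the Herlev
cervical-cell benchmark (917 cells, 7 classes).

These are reported evaluation numbers, rounded to two decimals as
published: a neighbour-count sweep comparing classification without
selection (All-Features) against PSO- and QPSO-driven wrapper selection
(P-Fuzzy / Q-Fuzzy), and a per-class breakdown at each method's best k.
They serve as worked-example inputs — e.g. checking that the F1 formula
reproduces each printed F1 from its printed precision/recall pair — not
as quantities this package claims to recompute from images.
"""

#: k -> method -> (precision, recall, f1, kappa); best All-Features k is 5,
#: best P-Fuzzy / Q-Fuzzy k is 4.
KNN_SWEEP = {
    2: {"all_features": (0.67, 0.74, 0.70, 0.66),
        "p_fuzzy": (0.73, 0.80, 0.76, 0.72),
        "q_fuzzy": (0.73, 0.79, 0.76, 0.71)},
    3: {"all_features": (0.68, 0.69, 0.68, 0.64),
        "p_fuzzy": (0.76, 0.77, 0.76, 0.72),
        "q_fuzzy": (0.77, 0.77, 0.77, 0.73)},
    4: {"all_features": (0.74, 0.74, 0.74, 0.70),
        "p_fuzzy": (0.83, 0.84, 0.83, 0.81),
        "q_fuzzy": (0.85, 0.86, 0.85, 0.83)},
    5: {"all_features": (0.76, 0.76, 0.76, 0.72),
        "p_fuzzy": (0.80, 0.81, 0.80, 0.76),
        "q_fuzzy": (0.80, 0.81, 0.80, 0.76)},
    6: {"all_features": (0.73, 0.73, 0.73, 0.68),
        "p_fuzzy": (0.74, 0.76, 0.75, 0.70),
        "q_fuzzy": (0.74, 0.75, 0.74, 0.69)},
    7: {"all_features": (0.69, 0.70, 0.69, 0.64),
        "p_fuzzy": (0.71, 0.72, 0.71, 0.67),
        "q_fuzzy": (0.73, 0.74, 0.73, 0.69)},
}

#: class -> method -> (precision, recall, f1); All-Features at k=5,
#: P-Fuzzy and Q-Fuzzy at k=4.
PER_CLASS = {
    "normal_superficial":  {"all_features": (0.83, 0.86, 0.84),
                            "p_fuzzy": (0.95, 0.91, 0.93),
                            "q_fuzzy": (0.95, 0.95, 0.95)},
    "normal_intermediate": {"all_features": (0.82, 0.74, 0.78),
                            "p_fuzzy": (0.89, 0.84, 0.86),
                            "q_fuzzy": (0.89, 0.89, 0.89)},
    "normal_columnar":     {"all_features": (0.63, 0.67, 0.65),
                            "p_fuzzy": (0.65, 0.72, 0.68),
                            "q_fuzzy": (0.61, 0.74, 0.67)},
    "carcinoma_in_situ":   {"all_features": (0.74, 0.83, 0.78),
                            "p_fuzzy": (0.81, 0.87, 0.84),
                            "q_fuzzy": (0.84, 0.90, 0.87)},
    "light_dysplastic":    {"all_features": (0.83, 0.78, 0.81),
                            "p_fuzzy": (0.88, 0.94, 0.91),
                            "q_fuzzy": (0.89, 0.97, 0.93)},
    "moderate_dysplastic": {"all_features": (0.69, 0.85, 0.76),
                            "p_fuzzy": (0.83, 0.96, 0.89),
                            "q_fuzzy": (0.89, 0.96, 0.93)},
    "severe_dysplastic":   {"all_features": (0.79, 0.62, 0.70),
                            "p_fuzzy": (0.86, 0.65, 0.74),
                            "q_fuzzy": (0.88, 0.61, 0.72)},
}

#: Rows whose printed F1 cannot be recovered to ±0.005 from the printed
#: 2-decimal P/R (it can from P/R values that round to the printed ones):
#: (table, row, method).
ROUNDING_LIMITED = {
    ("per_class", "moderate_dysplastic", "q_fuzzy"),
    ("per_class", "light_dysplastic", "all_features"),
    ("per_class", "severe_dysplastic", "all_features"),
}

#: Five worked examples: (precision, recall) -> published F1.
WORKED_EXAMPLES = {
    "f1_q_fuzzy_k4": (0.85, 0.86, 0.85),
    "f1_p_fuzzy_k4": (0.83, 0.84, 0.83),
    "f1_all_features_k5": (0.76, 0.76, 0.76),
    "f1_q_fuzzy_carcinoma_in_situ": (0.84, 0.90, 0.87),
    "f1_q_fuzzy_normal_superficial": (0.95, 0.95, 0.95),
}
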