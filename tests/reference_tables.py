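"""Published reference tables used as regression oracles.

Pooled 200-iteration test-set confusion matrices for six classifiers
(five base classifiers + majority voting) from a published cucumber-leaf
nitrogen-classification experiment, together with the metric values the
report prints for them.  Rows are actual classes D0..D3, columns predicted.
The evaluation module must reproduce the printed CCR, misclassified-%,
recall, precision and F values from these counts alone.
"""

REFERENCE_CLASSES = ("D0", "D1", "D2", "D3")

REFERENCE_CONFUSION = {
    "KNN": [[44872, 948, 0, 0],
            [1013, 40091, 768, 1229],
            [0, 430, 29490, 695],
            [0, 1519, 773, 33172]],
    "RBF": [[24241, 16740, 2950, 1889],
            [169, 36072, 4155, 2705],
            [0, 3168, 26837, 610],
            [14, 17809, 5543, 12098]],
    "LDA": [[43703, 1751, 366, 0],
            [673, 40845, 266, 1317],
            [0, 395, 29744, 476],
            [0, 458, 904, 34102]],
    "ANN-ICA": [[44794, 997, 29, 0],
                [1087, 40926, 133, 955],
                [0, 610, 29596, 409],
                [0, 915, 846, 33703]],
    "ANN-HS": [[44872, 899, 49, 0],
               [1079, 40914, 151, 957],
               [1, 617, 29581, 416],
               [0, 1008, 847, 33609]],
    "MV": [[44566, 1157, 96, 1],
           [1094, 40965, 132, 910],
           [8, 714, 29486, 407],
           [0, 1580, 788, 33096]],
}

REFERENCE_CCR = {
    "KNN": 95.24, "RBF": 64.03, "LDA": 95.73,
    "ANN-ICA": 96.14, "ANN-HS": 96.11, "MV": 95.55,
}

# columns: recall, accuracy, specificity, precision, F (percent);
# the report's recall is diagonal/column-total, precision diagonal/row-total
REFERENCE_METRICS = {
    "KNN": [[97.79231, 98.68905, 99.08583, 97.93103, 97.86162],
            [93.26091, 96.15259, 97.2771, 93.0164, 93.1385],
            [95.034, 98.22611, 99.05668, 96.32533, 95.67531],
            [94.51789, 97.22341, 98.03675, 93.53711, 94.02494]],
    "RBF": [[99.25074, 82.01636, 77.65825, 52.90485, 69.01942],
            [48.88534, 68.92509, 89.98789, 83.69179, 61.71957],
            [67.96758, 85.79975, 95.04128, 87.65964, 76.56776],
            [69.92255, 77.64791, 78.85736, 34.11347, 45.85529]],
    "LDA": [[98.48341, 98.15457, 98.01794, 95.37975, 96.90674],
            [94.00677, 96.82879, 97.94545, 94.76578, 94.38475],
            [95.08951, 98.40386, 99.27126, 97.15499, 96.11116],
            [95.00488, 97.91817, 98.82235, 96.15949, 95.57869]],
    "ANN-ICA": [[97.63083, 98.60188, 99.02519, 97.7608, 97.69577],
                [94.19536, 96.94436, 98.02753, 94.95371, 94.57302],
                [96.70631, 98.65802, 99.15395, 96.67157, 96.68894],
                [96.1103, 97.94602, 98.49586, 95.0344, 95.56932]],
    "ANN-HS": [[97.64972, 98.65699, 99.09759, 97.93103, 97.79018],
               [94.18942, 96.93468, 98.01631, 94.92587, 94.55621],
               [96.58156, 98.62237, 99.1414, 96.62257, 96.60206],
               [96.07512, 97.87916, 98.41753, 94.76934, 95.41777]],
    "MV": [[97.58693, 98.43423, 98.80345, 97.2632, 97.4248],
           [92.23028, 96.365, 98.04546, 95.0442, 93.6161],
           [96.66907, 98.57246, 99.05725, 96.31227, 96.49034],
           [96.17016, 97.57179, 97.98271, 93.32281, 94.72509]],
}

REFERENCE_MISCLASSIFIED = {
    "KNN": [2.11, 7.5, 3.81, 6.9],
    "RBF": [89.01, 19.48, 14.07, 193.13],
    "LDA": [4.84, 5.52, 2.92, 3.99],
    "ANN-ICA": [2.29, 5.31, 3.44, 5.22],
    "ANN-HS": [2.11, 5.34, 3.49, 5.51],
    "MV": [2.81, 5.21, 3.82, 7.15],
}

# effective- vs entire-wavelength summary rows (CCR % and four mean AUCs)
# used for the published paired t-test: t = -1.001, df = 4, p = 0.374
EFFECTIVE_ROW = [95.55, 0.998, 0.993, 0.996, 0.995]
ENTIRE_ROW = [96.14, 0.998, 0.994, 0.998, 0.996]
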