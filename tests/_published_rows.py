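"""Published confusion/correction counts with their printed metric values.

Read-level rows: (dataset, rule, TP, FN, FP, TN, Pr, Sp, Sn) — metrics
printed to 3 decimal places. Base-level rows: (dataset, algorithm, TP, FN,
FP, TN, WC, Sn, Sp, Gain, EBA) — EBA printed to 6 decimal places.
"""

READ_LEVEL_ROWS = [
    ("S4", 1, 44315371, 122066, 3718959, 6840510, 0.923, 0.648, 0.997),
    ("S4", 2, 44392266, 45171, 3873795, 6685674, 0.920, 0.633, 0.999),
    ("S4", 3, 44392266, 45171, 3873932, 6685537, 0.920, 0.633, 0.999),
    ("S4", 4, 44415654, 21783, 3905218, 6654251, 0.919, 0.630, 1.000),
    ("S4", 5, 44416777, 20660, 3926550, 6632919, 0.919, 0.628, 1.000),
    ("S5", 1, 40246703, 225848, 4161367, 5104888, 0.906, 0.551, 0.994),
    ("S5", 2, 40420872, 51679, 4422332, 4843923, 0.901, 0.523, 0.999),
    ("S5", 3, 40420999, 51552, 4422972, 4843283, 0.901, 0.523, 0.999),
    ("S5", 4, 40433782, 38769, 4435544, 4830711, 0.901, 0.521, 0.999),
    ("S5", 5, 40443582, 28969, 4442097, 4824158, 0.901, 0.521, 0.999),
    ("S6", 1, 51341705, 270694, 1354288, 4919653, 0.974, 0.784, 0.995),
    ("S6", 2, 51578979, 33420, 1681374, 4592567, 0.968, 0.732, 0.999),
    ("S6", 3, 51579033, 33366, 1681628, 4592313, 0.968, 0.732, 0.999),
    ("S6", 4, 51605360, 7039, 1684518, 4589423, 0.968, 0.732, 1.000),
    ("S6", 5, 51605719, 6680, 1690727, 4583214, 0.968, 0.731, 1.000),
]

BASE_LEVEL_ROWS = [
    ("S1", "baseline", 4780231, 28675648, 134010, 4249799767, 19494, 0.143, 1.000, 0.139, 0.004061),
    ("S1", "rule1", 1299909, 6308111, 3427119, 1143304758, 18463, 0.171, 0.997, -0.280, 0.014004),
    ("S1", "rule2", 9147518, 24304818, 158446, 4249775331, 23037, 0.273, 1.000, 0.269, 0.002512),
    ("S2", "baseline", 5665375, 8695457, 90366, 1946564438, 2788, 0.395, 1.000, 0.388, 0.000492),
    ("S2", "rule1", 2895901, 11462701, 745833, 1945908971, 5018, 0.202, 1.000, 0.150, 0.001730),
    ("S2", "rule2", 5371516, 8988883, 128454, 1946526350, 3221, 0.374, 1.000, 0.365, 0.000599),
    ("S3", "baseline", 18025179, 10286737, 605575, 6874673712, 44797, 0.637, 1.000, 0.615, 0.002479),
    ("S3", "rule1", 18806026, 9498842, 1940111, 6873336908, 51638, 0.664, 1.000, 0.596, 0.002738),
    ("S3", "rule2", 18290440, 10019429, 695540, 6874583747, 46844, 0.646, 1.000, 0.622, 0.002555),
    ("S4", "baseline", 5565750, 3453627, 17740, 3810574694, 5139, 0.617, 1.000, 0.615, 0.000922),
    ("S4", "rule1", 6365587, 2653084, 50006, 3810542428, 5845, 0.706, 1.000, 0.700, 0.000917),
    ("S4", "rule2", 5990892, 3028178, 19705, 3810572729, 5446, 0.664, 1.000, 0.662, 0.000908),
    ("S5", "baseline", 1690826, 3501370, 302635, 3259337078, 11016, 0.326, 1.000, 0.267, 0.006473),
    ("S5", "rule1", 1904825, 3286174, 481440, 3259158273, 12213, 0.367, 1.000, 0.274, 0.006371),
    ("S5", "rule2", 1802536, 3389315, 341530, 3259298183, 11361, 0.347, 1.000, 0.281, 0.006263),
    ("S6", "baseline", 4346955, 1083849, 16099, 4213859720, 1413, 0.800, 1.000, 0.797, 0.000325),
    ("S6", "rule1", 4939773, 490989, 37325, 4213838494, 1455, 0.910, 1.000, 0.903, 0.000294),
    ("S6", "rule2", 4449982, 980530, 19259, 4213856560, 1705, 0.819, 1.000, 0.816, 0.000383),
]
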