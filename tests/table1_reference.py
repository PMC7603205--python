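"""The published 27-row configuration table, transcribed verbatim.

Integer columns: nCr, nC'r (dilution-reduced), Nc' (circumferential),
Nr' (radial/mixed), Np' (positions).  Time columns are kept as printed
strings so tests can compare at the printed precision.

Known defects in the printed table, asserted against the model instead:
* (4, 40): Nr' printed malformed ("91,06440"); the decomposition gives
  9,106,440, which is what PRINTED_TABLE1 carries, with the row listed in
  INTEGER_TYPO_ROWS.
* (3, 48): Time printed 0.5 days, but 6624 positions at 10 s give 0.767.
* (2, 3): Time printed 0.0004, a truncation of 0.000463.
* (2, 3) and (4, 6): Time ML printed as truncations rather than roundings.
"""

# (r, n_rad): (nCr, nC'r, Nc', Nr', Np', time_printed, time_ml_printed)
PRINTED_TABLE1 = {
    (2, 2): (6, 4, 2, 2, 2, "0.0002", "0.000001"),
    (2, 3): (15, 12, 6, 6, 4, "0.0004", "0.000003"),
    (2, 4): (28, 24, 12, 12, 6, "0.0007", "0.000007"),
    (2, 6): (66, 60, 30, 30, 10, "0.001", "0.00002"),
    (2, 8): (120, 112, 56, 56, 14, "0.002", "0.00003"),
    (2, 10): (190, 180, 90, 90, 18, "0.002", "0.00005"),
    (2, 20): (780, 760, 380, 380, 38, "0.004", "0.0002"),
    (2, 30): (1770, 1740, 870, 870, 58, "0.007", "0.0005"),
    (2, 48): (4560, 4512, 2256, 2256, 94, "0.01", "0.0014"),
    (3, 3): (84, 27, 3, 24, 9, "0.001", "0.000002"),
    (3, 4): (220, 96, 12, 84, 24, "0.003", "0.000007"),
    (3, 6): (816, 432, 60, 372, 72, "0.008", "0.00004"),
    (3, 8): (2024, 1152, 168, 984, 144, "0.02", "0.0001"),
    (3, 10): (4060, 2400, 360, 2040, 240, "0.03", "0.0002"),
    (3, 20): (34_220, 21_600, 3420, 18_180, 1080, "0.13", "0.0021"),
    (3, 30): (117_480, 75_600, 12_180, 63_420, 2520, "0.3", "0.0073"),
    (3, 40): (280_840, 182_400, 29_640, 152_760, 4560, "0.5", "0.0179"),
    (3, 48): (487_344, 317_952, 51_888, 266_064, 6624, "0.5", "0.0313"),
    (4, 4): (1820, 256, 4, 252, 64, "0.007", "0.000002"),
    (4, 6): (10_626, 2592, 60, 2532, 432, "0.05", "0.00003"),
    (4, 8): (35_960, 10_240, 280, 9960, 1280, "0.15", "0.0002"),
    (4, 10): (91_390, 28_000, 840, 27_160, 2800, "0.3", "0.0005"),
    (4, 20): (1_581_580, 544_000, 19_380, 524_620, 27_200, "3.15", "0.0117"),
    (4, 30): (8_214_570, 2_916_000, 109_620, 2_806_380, 97_200, "11.3", "0.0661"),
    (4, 35): (15_329_615, 5_488_000, 209_440, 5_278_560, 156_800, "18.1", "0.1263"),
    (4, 40): (26_294_360, 9_472_000, 365_560, 9_106_440, 236_800, "27.4", "0.2204"),
    (4, 48): (54_870_480, 19_906_560, 778_320, 19_128_240, 414_720, "48", "0.4692"),
}

# rows whose printed integer cells are corrupted; values above are the
# model's (corrected) numbers
INTEGER_TYPO_ROWS = {(4, 40): "Nr'"}

# rows whose printed Time does not equal the position count x 10 s model
# at the printed precision (half-up rounding)
TIME_MISMATCH_ROWS = {(3, 48), (2, 3)}

# rows whose printed Time ML deviates from the single-ring model at the
# printed precision (truncated instead of rounded)
TIME_ML_MISMATCH_ROWS = {(2, 3), (4, 6)}


def printed_decimals(s: str) -> int:
    return len(s.split(".")[1]) if "." in s else 0
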