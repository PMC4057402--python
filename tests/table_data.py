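"""Published QTL summary tables used as worked-example inputs.

Two winter-cereal traits (winter-survival score and frost-damage score)
mapped in the same four-family DH population: per-QTL chromosome, peak
position with support interval, and the share of genotypic variance (pG)
overall and per family.  These printed numbers exercise the reporting
rules (overlap, major-QTL call, genome sums) without rerunning any scan.
"""

from mcqtl.scan import QTLRecord

FAMILIES = ["DH06", "DH07", "EAW74", "EAW78"]


def _rec(chrom, pos, lo, hi, pg, pg_fams):
    return QTLRecord(
        chromosome=chrom, position=pos, ci_lo=lo, ci_hi=hi, lod=float("nan"),
        pg_overall=pg, pg_family=dict(zip(FAMILIES, pg_fams)),
    )


WINTER_HARDINESS_QTL = [
    _rec("2A", 62.1, 58.0, 63.8, 2.2, (0.6, 3.6, 0.3, 0.2)),
    _rec("5A", 52.7, 51.6, 52.9, 14.1, (1.2, 0.2, 40.2, 0.0)),
    _rec("7A", 63.6, 63.5, 63.7, 2.3, (0.0, 0.5, 3.1, 3.3)),
    _rec("1B", 54.1, 53.2, 54.3, 12.5, (14.4, 17.4, 7.6, 18.8)),
    _rec("2B", 107.4, 107.0, 108.1, 2.9, (4.5, 3.4, 3.1, 4.1)),
    _rec("5B", 39.9, 39.3, 40.7, 2.8, (2.1, 2.2, 5.3, 1.3)),
    _rec("6B", 56.8, 55.3, 58.7, 2.0, (1.5, 6.8, 0.7, 0.2)),
    _rec("4R", 35.7, 35.3, 36.1, 2.6, (0.0, 0.2, 4.8, 2.3)),
    _rec("5R", 58.9, 58.6, 58.9, 24.1, (44.8, 20.4, 3.4, 29.8)),
]

FROST_TOLERANCE_QTL = [
    _rec("1A", 80.1, 80.0, 80.4, 2.6, (0.0, 8.3, 1.4, 1.5)),
    _rec("5A", 52.5, 51.6, 52.9, 12.4, (2.1, 0.5, 40.2, 0.3)),
    _rec("6A", 14.5, 14.0, 14.6, 2.2, (0.0, 13.1, 0.0, 0.2)),
    _rec("7A", 71.6, 66.8, 79.3, 3.4, (0.4, 4.1, 3.8, 1.9)),
    _rec("1B", 54.1, 53.2, 54.3, 16.3, (19.0, 15.4, 5.1, 25.3)),
    _rec("2B", 79.3, 78.5, 79.3, 2.9, (5.6, 3.4, 4.3, 4.1)),
    _rec("6B", 57.8, 55.3, 58.7, 1.9, (1.6, 2.5, 3.1, 0.6)),
    _rec("4R", 25.3, 25.1, 25.3, 3.0, (0.8, 4.5, 6.9, 0.0)),
    _rec("5R", 55.6, 55.4, 56.2, 14.7, (31.7, 9.0, 1.5, 18.2)),
]

# cross-validation summary (percent of genotypic variance)
CV_SUMMARY = {
    "winter_hardiness": {"pg_es": 52.5, "pg_ts": 31.3, "relative_bias": 40.4},
    "frost_tolerance": {"pg_es": 52.0, "pg_ts": 30.0, "relative_bias": 42.3},
}

# trial variance components of the two-location trait
VARIANCES = {"var_g": 3.00, "var_gxl": 0.33}
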