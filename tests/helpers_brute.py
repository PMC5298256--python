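"""Independent brute-force reference for the stress-test calculations.

Pure Python, explicit sorting, no shared code with the package: this is the
oracle the implementation is checked against.  Indices are 1-based lists.
"""

from __future__ import annotations

LAYOUT_14 = {
    "basal": [1, 2, 3, 4, 5],
    "oligo": [6, 7, 8],
    "fccp": [9, 10, 11],
    "antrot": [12, 13, 14],
    "basal_stat": [3, 4, 5],
}

LAYOUT_12 = {
    "basal": [1, 2, 3],
    "oligo": [4, 5, 6],
    "fccp": [7, 8, 9],
    "antrot": [10, 11, 12],
    "basal_stat": [2, 3],
}


def bf_median(values):
    s = sorted(values)
    n = len(s)
    if n % 2 == 1:
        return s[n // 2]
    return (s[n // 2 - 1] + s[n // 2]) / 2.0


def bf_mean(values):
    return sum(values) / len(values)


def bf_well_params(ocr, layout):
    """Six parameters from one OCR trace (plain list, 1-based layout)."""
    pick = lambda idx: [ocr[i - 1] for i in idx]
    nmitor = bf_median(pick(layout["antrot"]))
    pl = bf_median(pick(layout["oligo"])) - nmitor
    br = bf_mean(pick(layout["basal_stat"])) - nmitor
    mr = max(pick(layout["fccp"])) - nmitor
    return {
        "nmitor": nmitor,
        "pl": pl,
        "br": br,
        "atp": br - pl,
        "mr": mr,
        "src": mr - br,
    }


def bf_median_curve(traces):
    """Per-measurement median across replicate traces (lists of lists)."""
    n_meas = len(traces[0])
    return [bf_median([t[j] for t in traces]) for j in range(n_meas)]


def bf_group_params(ocr_traces, layout):
    """Group parameters: the well formulas applied to the median curve."""
    return bf_well_params(bf_median_curve(ocr_traces), layout)


def bf_standard_error(values):
    n = len(values)
    if n == 1:
        return 0.0
    m = bf_mean(values)
    var = sum((v - m) ** 2 for v in values) / (n - 1)
    return (var / n) ** 0.5
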