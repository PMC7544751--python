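"""Published benchmark values bundled for regression comparisons.

These are transcribed results of the extremity-dosimetry study this
package reproduces: the per-finger dose-response slopes and scenario
doses from its full-scale simulation, the thermoluminescent-dosimeter
Hp(0.07) measurements used to validate it, and literature
normalized-dose rows. They are reference data, never recomputed.
"""

from __future__ import annotations

__all__ = [
    "REFERENCE_SLOPES_GY_PER_DECAY",
    "REFERENCE_DOSES_MGY",
    "REFERENCE_SCENARIO",
    "REFERENCE_MEASUREMENTS",
    "LITERATURE_NORMALIZED_MSV_PER_GBQ",
]

#: Fitted dose-response slopes of the benchmark simulation, Gy per decay.
REFERENCE_SLOPES_GY_PER_DECAY = {
    "thumb": 1.82e-16,
    "index": 5.68e-15,
    "middle": 5.25e-15,
    "ring": 2.16e-15,
    "small": 1.07e-15,
}

#: Benchmark absorbed doses for the 300 MBq / 120 s scenario, mGy
#: (as printed; the thumb entry is inconsistent with its slope at
#: 3-decimal rounding, which gives 0.007).
REFERENCE_DOSES_MGY = {
    "thumb": 0.006,
    "index": 0.204,
    "middle": 0.189,
    "ring": 0.078,
    "small": 0.039,
}

#: Benchmark handling scenario.
REFERENCE_SCENARIO = {
    "activity_bq": 300e6,
    "handling_time_s": 120.0,
    "n_decays": 3.6e10,
}

#: Measured Hp(0.07) values, mSv: (worker_role, facility, finger) rows.
REFERENCE_MEASUREMENTS = [
    # nurse, diagnostic centre I
    ("nurse", "PET-I", "thumb", 0.044),
    ("nurse", "PET-I", "index", 0.160),
    ("nurse", "PET-I", "middle", 0.106),
    ("nurse", "PET-I", "ring", 0.002),
    ("nurse", "PET-I", "small", 0.064),
    # first nurse, diagnostic centre II
    ("nurse", "PET-II-a", "thumb", 0.052),
    ("nurse", "PET-II-a", "index", 0.269),
    ("nurse", "PET-II-a", "middle", 0.119),
    ("nurse", "PET-II-a", "ring", 0.077),
    ("nurse", "PET-II-a", "small", 0.079),
    # second nurse, diagnostic centre II
    ("nurse", "PET-II-b", "thumb", 0.078),
    ("nurse", "PET-II-b", "index", 0.188),
    ("nurse", "PET-II-b", "middle", 0.027),
    ("nurse", "PET-II-b", "ring", 0.050),
    ("nurse", "PET-II-b", "small", 0.060),
    # chemist, radiopharmaceutical production centre I (quality control)
    ("chemist", "RPC-I", "thumb", 0.015),
    ("chemist", "RPC-I", "index", 0.153),
    ("chemist", "RPC-I", "middle", 0.130),
    ("chemist", "RPC-I", "ring", 0.163),
    ("chemist", "RPC-I", "small", 0.056),
]

#: Literature maximum normalized doses, mSv/GBq:
#: study -> (range_low, range_high, mean, median).
LITERATURE_NORMALIZED_MSV_PER_GBQ = {
    "this_work": (0.13, 0.68, 0.35, 0.29),
    "quality_control_dispensing": (0.02, 0.85, 0.50, 0.35),
    "f18_preparation_a": (0.29, 0.85, 0.57, 0.57),
    "f18_preparation_b": (0.03, 2.06, 0.43, 0.25),
    "f18_preparation_c": (0.10, 4.43, 1.20, 0.83),
}
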