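"""Quantify site-specific editing from Sanger chromatogram peak heights.

The editing level is minor/(major+minor).  Base callers only report a
minor peak when it reaches 5% of the major peak, so the smallest
quantifiable level is 5/105 = 0.048.
"""

from apoedit import PeakPair, detection_threshold, editing_from_peaks

print(f"detection threshold: {detection_threshold(0.05):.3f}")

peaks = [
    PeakPair("TM7SF3", "C", 100.0, "T", 25.0),  # 20% edited
    PeakPair("EIF3I", "T", 80.0, "C", 20.0),    # edited T is now the MAJOR peak
    PeakPair("RFX7", "C", 100.0, "T", 3.0),     # below detection
]
for p in peaks:
    level, detected = editing_from_peaks(p)
    print(f"{p.site:>7}: minor fraction={level:.3f} detected={detected}")
# The reported level is the minor-peak fraction (at most 0.5).  When the
# edited base is the major peak (EIF3I), the minor fraction 0.2 is the
# residual reference signal, i.e. ~80% of transcripts are edited.
# Levels below the threshold are still reported but flagged undetected.
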