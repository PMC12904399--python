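"""Parse a Raven selection table, tile it into labeled 0.2 s segments,
and mine background-noise segments from the gaps between calls."""

import tempfile
from pathlib import Path

from sirenet import raven_io

# A small Raven-style table: two annotated calls on a 5 s recording.
raw = "\n".join(
    [
        "Selection\tView\tChannel\tBegin Time (s)\tEnd Time (s)\tLow Freq (Hz)\tHigh Freq (Hz)",
        "1\tSpectrogram 1\t1\t1.0000\t1.5000\t2400.0\t7100.0",
        "2\tSpectrogram 1\t1\t3.0000\t3.4000\t3100.0\t9300.0",
    ]
)
path = Path(tempfile.mkdtemp()) / "site.selections.txt"
path.write_text(raw + "\n")

table = raven_io.read_selection_table(path, recording_duration_s=5.0)
print(f"{len(table)} annotated calls, {table.total_call_seconds:.2f} s of vocalizations")

segments = raven_io.segment_and_label(table, window_s=0.2)
positives = [s for s in segments if s.label == "positive"]
print(f"{len(segments)} segments tile the recording; {len(positives)} are positive")
print("positive segment starts:", [round(s.start_s, 1) for s in positives])
# A segment is positive when any part of a call overlaps it, so the 0.5 s
# call at 1.0-1.5 s marks three 0.2 s slices (1.0, 1.2, 1.4) positive.

negatives = raven_io.mine_negatives(table, window_s=0.2)
print(f"{len(negatives)} background segments mined from the inter-call gaps")
# Gaps are [0, 1.0], [1.5, 3.0], [3.4, 5.0] -> 5 + 7 + 8 = 20 negatives.

manifest = raven_io.split_manifest(positives + negatives, train_fraction=0.8, seed=0)
print("split summary:", manifest.class_counts())
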