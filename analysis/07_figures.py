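"""Render all figures from the tables written by scripts 01-06."""

from pathlib import Path

from beliefrnn.figures import render_all

results = Path(__file__).resolve().parents[1] / "results"
written = render_all(results, results / "figures")
for path in written:
    print("wrote", path)
if not written:
    print("no input tables found — run the earlier analysis scripts first")
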