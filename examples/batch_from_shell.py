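"""Batch processing through the command-line interface.

Writes a handful of synthetic scenes to disk, then runs the dye-uptake
pipeline over the whole directory exactly as one would from a shell:

    myohisto synth --assay ebd --out-dir scenes/ --n-scenes 3 --seed 9
    myohisto ebd --input scenes/ --out results.csv --save-overlays qc/

and prints the resulting CSV. Per-image failures become warning rows
(exit code 2) rather than aborting the batch.
"""

import tempfile
from pathlib import Path

from click.testing import CliRunner

from myohisto.cli import main

runner = CliRunner()
with tempfile.TemporaryDirectory() as tmp:
    scenes = Path(tmp) / "scenes"
    out_csv = Path(tmp) / "results.csv"
    r = runner.invoke(main, ["synth", "--assay", "ebd", "--out-dir", str(scenes),
                             "--n-scenes", "3", "--seed", "9",
                             "--height", "256", "--width", "256",
                             "--n-fibers", "25"])
    print(r.output.strip())
    r = runner.invoke(main, ["ebd", "--input", str(scenes), "--out", str(out_csv)])
    assert r.exit_code == 0, r.output
    print(out_csv.read_text().strip())
    print((scenes / "truth.csv").read_text().strip())
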