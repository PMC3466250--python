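#!/usr/bin/env python
"""Per-read QC of the simulated library.

Reads the FASTQ written by 01_simulate_library.py (regenerating it
deterministically when absent), runs the quality/vector/cap/tail/
complexity cascade and writes the per-read disposition table and a QC
summary to results/.
"""

from __future__ import annotations

import subprocess
import sys
from collections import Counter
from pathlib import Path

from oligocap import seqio
from oligocap.preprocess import preprocess_read

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "library"
RESULTS = ROOT / "results"


def main() -> None:
    fastq = SCRATCH / "reads.fastq"
    if not fastq.exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "01_simulate_library.py")],
                       check=True)
    reads = list(seqio.read_seq_records(fastq, "fastq"))
    rows = []
    dispositions = Counter()
    caps = tails = 0
    for read in reads:
        ann = preprocess_read(read)
        disp = ann.discard_reason.value if ann.discard_reason else "kept"
        dispositions[disp] += 1
        caps += ann.cap_found
        tails += ann.tail_start is not None
        rows.append(
            {
                "read_id": read.id,
                "disposition": disp,
                "trim_start": ann.trimmed_span[0],
                "trim_end": ann.trimmed_span[1],
                "cap_found": ann.cap_found,
                "tail_start": ann.tail_start if ann.tail_start is not None else "",
            }
        )
    seqio.write_report_table(rows, RESULTS / "02_read_annotations.tsv")
    n5 = sum(1 for r in reads if r.id.endswith("_5p"))
    print(f"preprocessed {len(reads)} reads: {dict(dispositions)}")
    print(f"  cap tag found on {caps}/{n5} 5' reads; "
          f"poly(A) tail on {tails}/{len(reads) - n5} 3' reads")
    print(f"  table -> {RESULTS / '02_read_annotations.tsv'}")


if __name__ == "__main__":
    main()
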