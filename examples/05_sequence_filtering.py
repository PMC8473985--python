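"""Intact-receptor filtering of a nucleotide repertoire.

Generates intact receptor-like sequences, injects known defects (truncation,
premature stop, single-base deletion) and runs the pseudogene/duplicate
filter, printing the class report.
"""

import tempfile
from pathlib import Path

import numpy as np
from Bio import SeqIO

import orthodiv as od

rng = np.random.default_rng(0)
records = od.make_intact_repertoire(20, rng)
records.append(records[0][:])  # one exact duplicate
injected, truth = od.inject_sequence_defects(
    records[:20], {"too_short": 3, "premature_stop": 3, "frameshift": 2}, seed=1
)
injected.append(records[20])

with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "repertoire.fasta"
    SeqIO.write(injected, fasta, "fasta")
    kept, report = od.filter_repertoire(fasta)

print(report.to_string(index=False))
print(f"\n{len(kept)} intact sequences kept out of {len(injected)}")
# intact + pseudogene reasons + duplicate always sum to the input count;
# any sequence under 650 bp is a pseudogene regardless of its reading frame.
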