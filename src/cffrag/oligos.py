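"""Lambda-phage-derived spike-in and control oligonucleotides.

The catalog holds the synthetic ssDNA ladder oligos (nominal sizes 30, 50,
75, 100, 150 and 200 nt) used to measure length-dependent extraction
recovery, plus the two strandedness control oligos.  Sequences are stored
verbatim as printed by the oligo order sheet, including degenerate N
positions; actual string lengths may deviate from the nominal size by a
couple of nucleotides (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = ["OligoCatalog", "load_oligos", "LADDER_SIZES"]

_SEQUENCES: dict[str, str] = {
    "Lambda dsDNA Control": (
        "CAAACTGCGCAACTCGTGAAAGGTAGGCGGATCCCCTTCGAAGGAAAGACCTGATGCTTTTCGTGCGCGCAT"
        "AAAATACCTTGATACTGTGCCGGATGAAAGCGGTTCGCGACGAGTAGATGCAATTATGGTTTCTCCGCCAAG"
        "AATCTCTTTGCATTTATCAAGTGTTTCCTTCATTGATATTCCGAGAGCATCAATATGCAATGCTGTTGGGAT"
        "GGCAATTTTTACGCCTGTTTTGCTTTGCTCGACATAAAGATATCCATCTACGATATCAGACCACTTCATTTC"
        "GCATAAATCACCAACTCGTTGCCCGGTAACAACAGCCAGTTCCATTGCAAGTCTGAGCCAACATGGTGATGA"
        "TTCTGCTGCTTGATAAATTTTCAGGTATTCGTCAGCCGTAAGTCTTGATCTCCTTACCTCTGATTTTGCTGC"
        "GCGAGTGGCAGCGACATGGTTTGTTGT"
    ),
    "Lambda ssDNA Control": (
        "CCTGGCCAGAATGCAATAACGGGAGGCGCTGTGGCTGATTTCGATAACCTGTTCGATGCTGCCATTGCCCGC"
        "GCCGATGAAACGATACGCGGGTACATGGGAACGTCAGCCACCATTACATCCGGTGAGCAGTCAGGTGCGGTG"
        "ATACGTGGTGTTTTTGATGACCCTGAAAATATCAGCTATGCCGGACAGGGCGTGCGCGTTGAAGGCTCCAGC"
        "CCGTCCCTGTTTGTCCGGACTGATGAGGTGCGGCAGCTGCGGCGTGGAGACACGCTGACCATCGGTGAGGAA"
        "AATTTCTGGGTAGATCGGGTTTCGCCGGATGATGGCGGAAGTTGTCATCTCTGGCTTGGAC"
    ),
    "lambda 200": (
        "AAGGCGGAGAGTCAGTTCGCGGNNNNNNNNNNNNCGGCGCAACGTCGCCAGCTGTCTGCACAGGAGAAATCC"
        "CTGCTGGCGCATAAAGATGAGACGCTGGAGTACAAACGCCAGCTGGCTGCACTTGGCGACAAGGTTACGTAT"
        "CAGGAGCGCCTGAACGCGCTGGCGCAGCAGGCGGATAAATTCGCACAGCAGCAA"
    ),
    "lambda 150": (
        "GCGTCCACTGCATGTTATGCCGCGTTCGCCAGGCTTGCTGTACCATGTGCGCTGATTCTTGCGCTCAATACG"
        "TTGCAGGTTGCTTTCAATCTGTTTGTGGTATTCAGCCAGCACTGTAAGGTCTATCGGATTTAGTGCNNNNNN"
        "NNNNNN"
    ),
    "lambda 100": (
        "TCGTTAGTTTCTCCGGTGGCAGGACGTCAGCATATTTGCTCTGGCTAATGGAGCAAAAGCGACGGGCAGGTA"
        "AAGACGTGCATTACGTNNNNNNNNNNNN"
    ),
    "lambda 75": "TCGTATCGCATTTATTGACCCGGCAAACGGGAATGAAACGCCGATGTTTGTGGCGCAGGGCAANNNNNNNNNNNN",
    "lambda 50": "ACCGCTTCCCGGTGCCGTTCACTTCCCGAATAACCCGGANNNNNNNNNNNN",
    "lambda 30": "ACGCGGTGACGACTATCAGGAAANNNNNNN",
}

#: ladder record name -> nominal size in nt
LADDER_SIZES: dict[str, int] = {
    "lambda 30": 30,
    "lambda 50": 50,
    "lambda 75": 75,
    "lambda 100": 100,
    "lambda 150": 150,
    "lambda 200": 200,
}


@dataclass(frozen=True)
class OligoCatalog:
    """Named nucleotide strings over the alphabet {A, C, G, T, N}."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"record {name!r} contains non-ACGTN symbols: {sorted(bad)}")

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def ladder(self) -> dict[str, int]:
        """Ladder record name -> actual string length, in nominal-size order."""
        return {name: len(self.records[name]) for name in LADDER_SIZES}

    def to_fasta(self, path: str | Path, line_width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.records.items():
                fh.write(f">{name.replace(' ', '_')}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def load_oligos() -> OligoCatalog:
    """Return the packaged oligo catalog (ladder + strandedness controls)."""
    return OligoCatalog(records=dict(_SEQUENCES))
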