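"""Reference sequence access and a deterministic synthetic genome.

Trinucleotide-context classification and chromosome-arm copy-number
arithmetic both need a reference sequence. The package works against any
FASTA, but also provides a small synthetic genome (~1 Mb across two
contigs) generated deterministically from a fixed seed, with a miniature
``chr3`` whose p/q arm boundaries are declared. This keeps every analysis
runnable offline and byte-reproducible without shipping sequence data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_BASE_CODES = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: internal seed for the default reference; part of the package's fixed
#: conditions, independent of any simulation seed.
_REFERENCE_SEED = 20160513

DEFAULT_CONTIG_LENGTHS = {"chr1": 850_000, "chr3": 150_000}

#: arm layout of the synthetic chr3: p arm [0, 60 kb), q arm [60 kb, 150 kb).
DEFAULT_CHR3_ARMS = ("chr3", 0, 60_000, 150_000)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Genome:
    """In-memory reference with 0-based half-open ``fetch`` semantics."""

    contigs: dict[str, str]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.contigs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise KeyError(f"{chrom}:{start}-{end} outside contig bounds")
        return seq[start:end]

    def length(self, chrom: str) -> int:
        return len(self.contigs[chrom])

    def trinucleotide(self, chrom: str, pos: int) -> str:
        """Trinucleotide centred on 1-based position ``pos``.

        Raises ``KeyError`` at contig edges where a flank is missing.
        """
        if pos < 2 or pos > len(self.contigs[chrom]) - 1:
            raise KeyError(f"{chrom}:{pos} lacks a 5' or 3' flank")
        return self.fetch(chrom, pos - 2, pos + 1)

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos - 1, pos)

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})


def synthetic_genome(
    lengths: dict[str, int] | None = None, seed: int = _REFERENCE_SEED
) -> Genome:
    """Deterministic random-uniform ACGT genome (default two contigs, ~1 Mb)."""
    lengths = dict(DEFAULT_CONTIG_LENGTHS if lengths is None else lengths)
    rng = np.random.default_rng(seed)
    contigs = {}
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for name, n in lengths.items():
        if n < 3:
            raise ValueError(f"contig {name} too short: {n}")
        codes = rng.integers(0, 4, size=n)
        contigs[name] = base_bytes[codes].tobytes().decode("ascii")
    return Genome(contigs)


def pyrimidine_site_index(genome: Genome, chrom: str) -> dict[str, np.ndarray]:
    """Map each pyrimidine-centred trinucleotide to its 1-based positions.

    Only interior positions (both flanks present) whose reference base is C
    or T are indexed; the simulator places variants at such sites so that
    every drawn 96-context has a matching reference trinucleotide.
    """
    seq = genome.contigs[chrom]
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for b, i in _BASE_CODES.items():
        lut[ord(b)] = i
    c = lut[codes]
    trin = c[:-2] * 16 + c[1:-1] * 4 + c[2:]
    centre = c[1:-1]
    index: dict[str, np.ndarray] = {}
    for f in range(4):
        for mid in (1, 3):  # C or T centre
            for t in range(4):
                tid = f * 16 + mid * 4 + t
                mask = (trin == tid) & ((centre == 1) | (centre == 3))
                pos = np.nonzero(mask)[0] + 2  # 1-based centre position
                index[BASES[f] + BASES[mid] + BASES[t]] = pos
    return index
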