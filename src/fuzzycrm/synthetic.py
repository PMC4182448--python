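"""Synthetic TFBS landscapes with known ground truth.

The generator emulates the input regime of a genome-wide screen: a uniform
background of binding-site calls spread over a set of chromosomes, plus
optional *planted modules* — loci where a chosen TF subset co-occurs
within a small window, standing in for real cis-regulatory modules. A
configuration with no planted modules is the pure-noise randomization
control: any itemset the pipeline reports on it is a false positive.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import TFBSRecord

REJECTION_CAP = 1000


@dataclass(frozen=True)
class PlantedModule:
    """A TF subset to co-locate at ``n_loci`` random loci within ``window`` bp."""

    tfs: tuple[str, ...]
    n_loci: int
    window: int

    def __post_init__(self) -> None:
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if not self.tfs:
            raise ValueError("planted module needs at least one TF")


@dataclass(frozen=True)
class PlantedLocus:
    """Ground-truth record of one planted module occurrence."""

    chrom: str
    start: int
    end: int
    tfs: tuple[str, ...]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic landscape.

    Background sites get uniform TF labels (or ``tf_frequencies`` when
    supplied, to emulate the skewed TF frequencies of real annotation
    sets) and uniform positions per chromosome, chromosomes weighted by
    length. ``window`` should stay below the clustering threshold so a
    planted locus lands in a single cluster.
    """

    chrom_lengths: dict[str, int]
    tf_alphabet: list[str]
    n_background_sites: int
    site_length: int = 10
    planted_modules: list[PlantedModule] = field(default_factory=list)
    seed: int = 0
    tf_frequencies: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("need at least one chromosome")
        if self.n_background_sites < 0:
            raise ValueError("n_background_sites must be >= 0")
        if self.site_length <= 0:
            raise ValueError("site_length must be > 0")
        for L in self.chrom_lengths.values():
            if L <= self.site_length:
                raise ValueError("chromosomes must be longer than site_length")
        alphabet = set(self.tf_alphabet)
        for m in self.planted_modules:
            missing = set(m.tfs) - alphabet
            if missing:
                raise ValueError(f"planted TFs not in alphabet: {sorted(missing)}")
        if self.tf_frequencies is not None:
            if len(self.tf_frequencies) != len(self.tf_alphabet):
                raise ValueError("tf_frequencies length must match tf_alphabet")
            if not np.isclose(sum(self.tf_frequencies), 1.0):
                raise ValueError("tf_frequencies must sum to 1")


def generate(config: SyntheticConfig) -> tuple[list[TFBSRecord], list[PlantedLocus]]:
    """Draw a synthetic site list and its ground-truth planted loci.

    Deterministic given ``config.seed``. Background sites come first, then
    planted sites module by module. Within a planted locus, sites are
    rejection-sampled to be pairwise non-overlapping; exceeding the
    rejection cap raises with the locus index.
    """
    rng = np.random.default_rng(config.seed)
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    L = config.site_length

    sites: list[TFBSRecord] = []
    for _ in range(config.n_background_sites):
        ci = rng.choice(len(chroms), p=chrom_p)
        chrom = chroms[ci]
        start = int(rng.integers(0, config.chrom_lengths[chrom] - L))
        tf = str(rng.choice(config.tf_alphabet, p=config.tf_frequencies))
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(TFBSRecord(tf, chrom, start, start + L, strand))

    truth: list[PlantedLocus] = []
    for m in config.planted_modules:
        half = m.window // 2
        for locus_idx in range(m.n_loci):
            ci = rng.choice(len(chroms), p=chrom_p)
            chrom = chroms[ci]
            clen = config.chrom_lengths[chrom]
            anchor = int(rng.integers(half, max(half + 1, clen - half)))
            lo = max(0, anchor - half)
            hi = min(clen - L, anchor + half - L)
            if hi < lo:
                hi = lo
            placed: list[tuple[int, int]] = []
            for tf in m.tfs:
                for attempt in range(REJECTION_CAP):
                    start = int(rng.integers(lo, hi + 1))
                    if all(start >= e or start + L <= b for b, e in placed):
                        placed.append((start, start + L))
                        strand = "+" if rng.random() < 0.5 else "-"
                        sites.append(TFBSRecord(tf, chrom, start, start + L, strand))
                        break
                else:
                    raise RuntimeError(
                        f"could not place non-overlapping site for {tf!r} at planted "
                        f"locus {locus_idx} of module {m.tfs} after {REJECTION_CAP} attempts"
                    )
            truth.append(
                PlantedLocus(
                    chrom=chrom,
                    start=min(b for b, _ in placed),
                    end=max(e for _, e in placed),
                    tfs=m.tfs,
                )
            )
    return sites, truth
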