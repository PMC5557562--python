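"""Synthetic annotated proteins with planted methylation-context motifs.

Real arginine-methylation data is dominated by glycine/arginine-rich (GAR)
contexts around the modified arginine. The generator emulates that signal
in its simplest usable form: background residues are drawn i.i.d. from a
configurable composition (uniform, with arginine boosted so every protein
carries several candidate sites), a configurable fraction of arginines is
flagged methylated, and each methylated site has glycines planted at
nearby offsets with a configurable per-offset probability. Unmethylated
arginines keep pure background context, so the positive/negative contrast
is exactly the planted enrichment and nothing else.

The generator writes standard FASTA plus the site TSV consumed by
:func:`metharg.dataset.load_annotated_proteins`, so the real readers are
exercised rather than bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .dataset import AnnotatedProtein, load_annotated_proteins
from .scales import AMINO_ACIDS


def _default_background() -> Dict[str, float]:
    # uniform over 20 residues with R boosted to 0.08 so proteins carry
    # several arginines; the rest share the remaining mass equally
    p_other = (1.0 - 0.08) / 19.0
    bg = {aa: p_other for aa in AMINO_ACIDS}
    bg["R"] = 0.08
    return bg


def _default_motif() -> List[Tuple[int, str, float]]:
    # GAR-like context: glycine at the +/-1 and +/-2 offsets with prob 0.8
    return [(-2, "G", 0.8), (-1, "G", 0.8), (1, "G", 0.8), (2, "G", 0.8)]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    ``motif`` is a list of ``(offset, residue, probability)`` triples,
    offsets relative to the methylated arginine (never 0);
    ``methylation_rate`` is the per-arginine probability of being flagged
    methylated.
    """

    n_proteins: int = 300
    length_range: Tuple[int, int] = (60, 300)
    background: Dict[str, float] = field(default_factory=_default_background)
    motif: List[Tuple[int, str, float]] = field(default_factory=_default_motif)
    methylation_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.length_range[0] < 30 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be [lo, hi] with lo >= 30")
        if set(self.background) != set(AMINO_ACIDS):
            raise ValueError("background must cover exactly the 20 residues")
        total = sum(self.background.values())
        if not np.isclose(total, 1.0):
            raise ValueError("background probabilities must sum to 1")
        if any(p < 0 for p in self.background.values()):
            raise ValueError("background probabilities must be non-negative")
        if self.background["R"] <= 0:
            raise ValueError("background must allow arginine")
        for off, res, p in self.motif:
            if off == 0:
                raise ValueError("motif offsets must be nonzero")
            if res not in AMINO_ACIDS:
                raise ValueError(f"invalid motif residue {res!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError("motif probabilities must be in [0, 1]")
        if not 0.0 <= self.methylation_rate <= 1.0:
            raise ValueError("methylation_rate must be in [0, 1]")


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A motif-free configuration: positives and negatives share one
    distribution, so downstream discrimination should be at chance."""
    cfg = SyntheticConfig(seed=seed, **overrides)
    cfg.motif = [(off, res, 0.0) for off, res, _ in cfg.motif]
    return cfg


def generate_synthetic_dataset(config: SyntheticConfig) -> List[AnnotatedProtein]:
    """Sample annotated proteins under ``config``; reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    letters = list(AMINO_ACIDS)
    probs = np.array([config.background[aa] for aa in letters])
    proteins: List[AnnotatedProtein] = []
    for i in range(config.n_proteins):
        n = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = list(rng.choice(letters, size=n, p=probs))
        r_pos = [j + 1 for j, aa in enumerate(seq) if aa == "R"]
        flags = rng.random(len(r_pos)) < config.methylation_rate
        methylated = {p for p, f in zip(r_pos, flags) if f}
        for p in sorted(methylated):
            for off, res, prob in config.motif:
                j = p - 1 + off
                if not 0 <= j < n:
                    continue
                if (j + 1) in methylated:
                    continue  # never overwrite a methylated arginine
                if rng.random() < prob:
                    seq[j] = res
        # planting may overwrite unmethylated arginines; annotations are
        # untouched, so they stay valid by construction
        proteins.append(
            AnnotatedProtein(f"syn{i:04d}", "".join(seq), frozenset(methylated))
        )
    return proteins


def write_fasta_and_sites(
    proteins: Sequence[AnnotatedProtein],
    fasta_path: Union[str, Path],
    sites_path: Union[str, Path],
) -> None:
    """Write the generator output in the dataset module's input dialect."""
    with open(fasta_path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
    with open(sites_path, "w") as fh:
        fh.write("protein_id\tposition\n")
        for p in proteins:
            for pos in sorted(p.methylated_positions):
                fh.write(f"{p.id}\t{pos}\n")


def generate_to_files(
    config: SyntheticConfig,
    fasta_path: Union[str, Path],
    sites_path: Union[str, Path],
) -> List[AnnotatedProtein]:
    """Generate, write FASTA + sites, and re-read through the real loaders.

    Returning the re-loaded records guarantees the files round-trip.
    """
    proteins = generate_synthetic_dataset(config)
    write_fasta_and_sites(proteins, fasta_path, sites_path)
    return load_annotated_proteins(fasta_path, sites_path)
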