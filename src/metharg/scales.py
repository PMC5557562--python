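"""Embedded per-residue physicochemical scales.

All scales are shipped as plain-text TSV resources under ``metharg/data`` so
they can be audited against their published sources. Lookup semantics for the
padding symbol ``X`` are uniform: it carries no physicochemical signal and
maps to 0.0 in every scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Tuple

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
#: 21-letter alphabet used by peptide windows: 20 standard residues + padding.
ALPHABET: str = AMINO_ACIDS + "X"
#: Nonstandard letters tolerated in input sequences but excluded from windows.
NONSTANDARD: frozenset = frozenset("BZUO")

SCALE_NAMES: Tuple[str, ...] = (
    "atchley_1",
    "atchley_2",
    "atchley_3",
    "atchley_4",
    "atchley_5",
    "kd_hydrophobicity",
    "vdw_volume",
    "asa_propensity",
    "disorder_propensity",
)


@dataclass(frozen=True)
class ScaleTable:
    """A named per-residue numeric scale over the 20 standard amino acids.

    ``X`` is handled at lookup time (always 0.0) and never stored.
    """

    name: str
    values: Dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(self.values)
            extra = set(self.values) - set(AMINO_ACIDS)
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )

    def lookup(self, residue: str) -> float:
        """Value for one residue; the padding symbol X encodes as 0.0."""
        if residue == "X":
            return 0.0
        try:
            return self.values[residue]
        except KeyError:
            raise ValueError(
                f"unknown residue {residue!r} for scale {self.name!r}"
            ) from None


def residue_scale_lookup(residue: str, scale: ScaleTable) -> float:
    """Functional alias for :meth:`ScaleTable.lookup`."""
    return scale.lookup(residue)


def _read_tsv(filename: str) -> List[List[str]]:
    text = resources.files("metharg.data").joinpath(filename).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _load_single_scale(filename: str, name: str) -> ScaleTable:
    rows = _read_tsv(filename)
    header, body = rows[0], rows[1:]
    assert header == ["residue", "value"], filename
    return ScaleTable(name, {r: float(v) for r, v in body})


@lru_cache(maxsize=1)
def builtin_scales() -> Dict[str, ScaleTable]:
    """All embedded scales, keyed by canonical name."""
    scales: Dict[str, ScaleTable] = {}
    rows = _read_tsv("atchley_factors.tsv")
    header, body = rows[0], rows[1:]
    for j, name in enumerate(header[1:], start=1):
        scales[name] = ScaleTable(name, {row[0]: float(row[j]) for row in body})
    scales["kd_hydrophobicity"] = _load_single_scale(
        "kyte_doolittle.tsv", "kd_hydrophobicity"
    )
    scales["vdw_volume"] = _load_single_scale("vdw_volume.tsv", "vdw_volume")
    scales["asa_propensity"] = _load_single_scale(
        "asa_propensity.tsv", "asa_propensity"
    )
    scales["disorder_propensity"] = _load_single_scale(
        "disorder_propensity.tsv", "disorder_propensity"
    )
    return scales


@lru_cache(maxsize=1)
def pka_set() -> Dict[str, Tuple[float, int]]:
    """Bjellqvist-style pKa set: group -> (pKa, sign).

    Groups are the free termini (``nterm``, ``cterm``) and the ionizable side
    chains C, D, E, H, K, R, Y. ``sign`` is +1 for a group that is positive
    when protonated and -1 for a group that is negative when deprotonated.
    """
    rows = _read_tsv("pka_bjellqvist.tsv")
    return {g: (float(p), int(s)) for g, p, s in rows[1:]}
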