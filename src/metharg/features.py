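"""Peptide-window feature encoding.

Each window of odd length L is encoded into exactly ``10*L + 4`` named
features, family-major and position-minor:

* per position (offsets -(L-1)/2 ... +(L-1)/2, 0 = the central arginine):
  the five Atchley factors, the positional amino-acid frequency learned from
  the positive training windows, a predicted accessibility score, a
  predicted disorder score, Kyte-Doolittle hydrophobicity, and the
  van der Waals residue volume;
* four whole-peptide globals: average van der Waals volume, GRAVY, net
  charge at pH 7, and the isoelectric point.

For L = 19/23/27/31/35 this yields 194/234/274/314/354 features. Padding X
is physicochemically silent: per-residue scales encode it as 0, global
averages skip it, and the charge model ignores it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Protocol, Tuple, Union

import numpy as np
import pandas as pd

from .dataset import POSITIVE, PeptideWindow, WindowDataset
from .scales import ALPHABET, AMINO_ACIDS, ScaleTable, builtin_scales, pka_set

GLOBAL_FEATURES = ("avg_vdwv", "gravy", "net_charge", "pI")
POSITIONAL_FAMILIES = (
    "atchley_1",
    "atchley_2",
    "atchley_3",
    "atchley_4",
    "atchley_5",
    "aafreq",
    "asa",
    "disorder",
    "hydro",
    "vdwv",
)


def offsets(window_length: int) -> List[int]:
    """Window position labels: -(L-1)/2 ... 0 ... +(L-1)/2."""
    half = window_length // 2
    return list(range(-half, half + 1))


def _pos_str(p: int) -> str:
    return "0" if p == 0 else f"{p:+d}"


def feature_names(window_length: int) -> List[str]:
    """Canonical feature-name order for a window length (family-major)."""
    names = [
        f"{family}_{_pos_str(p)}"
        for family in POSITIONAL_FAMILIES
        for p in offsets(window_length)
    ]
    names.extend(GLOBAL_FEATURES)
    return names


# ---------------------------------------------------------------------------
# Positional amino-acid frequency
# ---------------------------------------------------------------------------


@dataclass
class PositionalFrequencyTable:
    """21 x L column-normalized frequency matrix fit on positive windows.

    Rows are the 20 standard residues plus X; columns are window offsets.
    Each column sums to 1.
    """

    window_length: int
    frequencies: pd.DataFrame  # index: 21 letters; columns: offsets

    def lookup(self, residue: str, position: int) -> float:
        return float(self.frequencies.at[residue, position])

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.frequencies.to_csv(path, sep="\t", index_label="residue")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "PositionalFrequencyTable":
        df = pd.read_csv(path, sep="\t", index_col="residue")
        df.columns = [int(c) for c in df.columns]
        return cls(len(df.columns), df)


def fit_positional_frequency(
    positive_train: WindowDataset,
) -> PositionalFrequencyTable:
    """Position-wise residue frequencies from the positive training windows."""
    if len(positive_train) == 0:
        raise ValueError("cannot fit frequencies on an empty dataset")
    L = positive_train.window_length
    counts = np.zeros((len(ALPHABET), L))
    row = {aa: i for i, aa in enumerate(ALPHABET)}
    for w in positive_train:
        for j, aa in enumerate(w.peptide):
            counts[row[aa], j] += 1
    freq = counts / len(positive_train)
    df = pd.DataFrame(freq, index=list(ALPHABET), columns=offsets(L))
    return PositionalFrequencyTable(L, df)


def positional_frequency_feature(
    window: PeptideWindow, table: PositionalFrequencyTable
) -> np.ndarray:
    """Per-position frequency-of-observed-residue vector of length L."""
    if len(window) != table.window_length:
        raise ValueError("window length does not match frequency table")
    return np.array(
        [
            table.lookup(aa, p)
            for aa, p in zip(window.peptide, offsets(len(window)))
        ]
    )


# ---------------------------------------------------------------------------
# Whole-peptide physicochemical globals
# ---------------------------------------------------------------------------


def global_scale_features(peptide: str) -> Tuple[float, float]:
    """(GRAVY, average van der Waals volume) over the non-X residues.

    Padding is excluded from the average so short-context windows are not
    diluted toward zero.
    """
    scales = builtin_scales()
    core = [aa for aa in peptide if aa != "X"]
    if not core:
        raise ValueError("peptide has no non-X residues")
    kd = scales["kd_hydrophobicity"]
    vdw = scales["vdw_volume"]
    gravy = sum(kd.lookup(aa) for aa in core) / len(core)
    avg_vdwv = sum(vdw.lookup(aa) for aa in core) / len(core)
    return gravy, avg_vdwv


def net_charge(peptide: str, pH: float = 7.0) -> float:
    """Peptide net charge by the Henderson-Hasselbalch sum.

    Free N- and C-termini plus the ionizable side chains (C, D, E, H, K, R,
    Y) contribute; the Bjellqvist-style pKa set is embedded under
    ``metharg/data``. X is ignored.
    """
    pkas = pka_set()
    core = [aa for aa in peptide if aa != "X"]
    if not core:
        raise ValueError("peptide has no non-X residues")
    unknown = set(core) - set(AMINO_ACIDS)
    if unknown:
        raise ValueError(f"invalid residues for charge model: {sorted(unknown)}")

    def group_charge(pka: float, sign: int) -> float:
        if sign > 0:  # base: +1 when protonated
            return 1.0 / (1.0 + 10.0 ** (pH - pka))
        return -1.0 / (1.0 + 10.0 ** (pka - pH))

    total = group_charge(*pkas["nterm"]) + group_charge(*pkas["cterm"])
    for aa in core:
        if aa in pkas:
            total += group_charge(*pkas[aa])
    return total


def isoelectric_point(peptide: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, found by bisection on [0, 14].

    The Henderson-Hasselbalch charge is strictly decreasing in pH, so the
    root is unique; iteration stops once ``|net_charge| < tol``.
    """
    lo, hi = 0.0, 14.0
    c_lo, c_hi = net_charge(peptide, lo), net_charge(peptide, hi)
    if c_lo < 0 or c_hi > 0:
        raise ValueError("no charge sign change on [0, 14]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(peptide, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Accessibility / disorder provider
# ---------------------------------------------------------------------------


class PropertyProvider(Protocol):
    """Contract for per-residue accessibility and disorder predictors.

    ``predict`` returns two vectors (accessibility-like, disorder-like) of
    the peptide's length, each bounded in [0, 1]. Real structure-based
    predictors can be plugged in through this interface.
    """

    name: str

    def predict(self, peptide: str) -> Tuple[np.ndarray, np.ndarray]: ...


class SmoothedPropensityProvider:
    """Deterministic provider: min-max-scaled per-residue propensity scales,
    averaged over a sliding window.

    This is an explicit sequence-only stand-in for external structure
    predictors, not a re-implementation of any of them. Each residue's score
    is the mean scaled propensity of the non-X residues within
    ``half_window`` positions; X positions score 0.5 (uninformative).
    """

    def __init__(
        self,
        asa_scale: Optional[ScaleTable] = None,
        disorder_scale: Optional[ScaleTable] = None,
        half_window: int = 3,
        name: str = "default",
    ) -> None:
        scales = builtin_scales()
        self.name = name
        self.half_window = half_window
        self._scaled = {}
        for key, scale in (
            ("asa", asa_scale or scales["asa_propensity"]),
            ("disorder", disorder_scale or scales["disorder_propensity"]),
        ):
            vals = scale.values
            lo, hi = min(vals.values()), max(vals.values())
            self._scaled[key] = {
                aa: (v - lo) / (hi - lo) for aa, v in vals.items()
            }

    def _profile(self, peptide: str, key: str) -> np.ndarray:
        scaled = self._scaled[key]
        n = len(peptide)
        out = np.empty(n)
        for i, aa in enumerate(peptide):
            if aa == "X":
                out[i] = 0.5
                continue
            lo, hi = max(0, i - self.half_window), min(n, i + self.half_window + 1)
            vals = [scaled[b] for b in peptide[lo:hi] if b != "X"]
            out[i] = float(np.mean(vals))
        return out

    def predict(self, peptide: str) -> Tuple[np.ndarray, np.ndarray]:
        return self._profile(peptide, "asa"), self._profile(peptide, "disorder")


def default_property_provider() -> SmoothedPropensityProvider:
    """The built-in deterministic accessibility/disorder provider."""
    return SmoothedPropensityProvider()


# ---------------------------------------------------------------------------
# Window encoding
# ---------------------------------------------------------------------------


@dataclass
class FeatureVector:
    """Named, ordered features for one window (length ``10*L + 4``)."""

    names: List[str]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.names)


def encode_window(
    window: PeptideWindow,
    table: PositionalFrequencyTable,
    provider: Optional[PropertyProvider] = None,
) -> FeatureVector:
    """Encode one window into its full named feature vector."""
    if len(window) != table.window_length:
        raise ValueError("window length does not match frequency table")
    provider = provider or default_property_provider()
    scales = builtin_scales()
    pep = window.peptide
    asa, disorder = provider.predict(pep)

    blocks = []
    for factor in ("atchley_1", "atchley_2", "atchley_3", "atchley_4", "atchley_5"):
        s = scales[factor]
        blocks.append([s.lookup(aa) for aa in pep])
    blocks.append(positional_frequency_feature(window, table))
    blocks.append(asa)
    blocks.append(disorder)
    blocks.append([scales["kd_hydrophobicity"].lookup(aa) for aa in pep])
    blocks.append([scales["vdw_volume"].lookup(aa) for aa in pep])

    gravy, avg_vdwv = global_scale_features(pep)
    globals_ = [avg_vdwv, gravy, net_charge(pep, 7.0), isoelectric_point(pep)]

    values = np.concatenate([np.asarray(b, dtype=float) for b in blocks] + [globals_])
    return FeatureVector(feature_names(len(window)), values)


def encode_dataset(
    windows: Union[WindowDataset, Iterable[PeptideWindow]],
    table: PositionalFrequencyTable,
    provider: Optional[PropertyProvider] = None,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Encode a window collection into a feature matrix plus a label vector.

    Returns ``(X, y)`` where ``X`` is a DataFrame with the canonical feature
    columns and ``y`` is 1 for positive windows, 0 otherwise.
    """
    provider = provider or default_property_provider()
    wlist = list(windows)
    if not wlist:
        raise ValueError("no windows to encode")
    rows = [encode_window(w, table, provider).values for w in wlist]
    X = pd.DataFrame(np.vstack(rows), columns=feature_names(len(wlist[0])))
    y = np.array([1 if w.label == POSITIVE else 0 for w in wlist])
    return X, y
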