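"""Reaction featurization and label binarization.

A catalytic asymmetric hydrogenation reaction is described by the olefin
substrate, the chiral ligand, and the solvent (all as SMILES), the metal
centre, an additive flag, and three continuous conditions (temperature,
H2 pressure, catalyst loading).  Each reaction is encoded as a fixed
1544-dimensional vector:

    [olefin Morgan FP 512 | ligand FP 512 | solvent FP 512 |
     metal one-hot 3 (Ir, Rh, Ru) | additive one-hot 2 | T | P | loading]

Morgan fingerprints use radius 2 and 512 bits.  The enantioselectivity
label is binary: 1 when %ee strictly exceeds the threshold (default 80),
0 otherwise (ties go to the low class).  Condition scalars are optionally
z-standardized with statistics fit on training data only, so that raw
bar/Celsius magnitudes do not dominate binary fingerprint bits in
distance-based kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ReactionRecord",
    "ConditionScaler",
    "FeaturizationError",
    "METALS",
    "FEATURE_DIM",
    "morgan_fingerprint",
    "maccs_fingerprint",
    "encode_reaction",
    "encode_reactions",
    "binarize_ee",
    "feature_layout",
]

METALS = ("Ir", "Rh", "Ru")
FP_BITS = 512
FP_RADIUS = 2
#: 3 x 512 fingerprint bits + 3 metal slots + 2 additive slots + 3 conditions
FEATURE_DIM = 3 * FP_BITS + len(METALS) + 2 + 3


class FeaturizationError(ValueError):
    pass


@dataclass(frozen=True)
class ReactionRecord:
    """One literature reaction."""

    reaction_id: str
    olefin: str
    ligand: str
    solvent: str
    metal: str
    additive_present: bool
    temperature: float   # degrees Celsius
    pressure: float      # bar
    catalyst_loading: float  # mol%
    ee: float            # percent enantiomeric excess in [0, 100]
    year: int

    def validate(self) -> None:
        if not (0.0 <= self.ee <= 100.0):
            raise FeaturizationError(
                f"{self.reaction_id}: ee={self.ee} outside [0, 100]")
        if self.metal not in METALS:
            raise FeaturizationError(
                f"{self.reaction_id}: unknown metal {self.metal!r} "
                f"(supported: {METALS})")
        if self.year < 1900:
            raise FeaturizationError(f"{self.reaction_id}: year {self.year} < 1900")
        for name in ("temperature", "pressure", "catalyst_loading"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise FeaturizationError(
                    f"{self.reaction_id}: missing/non-finite {name}")
        for role in ("olefin", "ligand", "solvent"):
            _mol_from_smiles(getattr(self, role))


def _mol_from_smiles(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    return mol


_MORGAN_GENS: dict = {}


def _morgan_gen(n_bits: int, radius: int):
    key = (n_bits, radius)
    if key not in _MORGAN_GENS:
        _MORGAN_GENS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits)
    return _MORGAN_GENS[key]


def morgan_fingerprint(smiles: str, n_bits: int = FP_BITS,
                       radius: int = FP_RADIUS) -> np.ndarray:
    """Hashed circular (Morgan/ECFP-like) fingerprint as a 0/1 vector.

    SMILES are parsed to a molecule first, so spelling variants of the
    same structure give bit-identical fingerprints.
    """
    mol = _mol_from_smiles(smiles)
    fp = _morgan_gen(int(n_bits), int(radius)).GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.float64)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


def maccs_fingerprint(smiles: str) -> np.ndarray:
    """166-bit MACCS structural key vector (RDKit's unused bit 0 dropped)."""
    mol = _mol_from_smiles(smiles)
    keys = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(167, dtype=np.float64)
    arr[list(keys.GetOnBits())] = 1.0
    return arr[1:]


@dataclass
class ConditionScaler:
    """Affine z-scaler for the three condition columns (fit on training data)."""

    mean_: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale_: np.ndarray = field(default_factory=lambda: np.ones(3))

    def fit(self, records) -> "ConditionScaler":
        C = np.array([[r.temperature, r.pressure, r.catalyst_loading]
                      for r in records], dtype=float)
        self.mean_ = C.mean(axis=0)
        sd = C.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, conditions: np.ndarray) -> np.ndarray:
        return (np.asarray(conditions, dtype=float) - self.mean_) / self.scale_

    def to_dict(self):
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d):
        return cls(mean_=np.asarray(d["mean"], float),
                   scale_=np.asarray(d["scale"], float))


def encode_reaction(record: ReactionRecord,
                    condition_scaler: ConditionScaler | None = None) -> np.ndarray:
    """Encode one reaction into the 1544-dimensional representation."""
    record.validate()
    parts = [
        morgan_fingerprint(record.olefin),
        morgan_fingerprint(record.ligand),
        morgan_fingerprint(record.solvent),
    ]
    metal = np.zeros(len(METALS))
    metal[METALS.index(record.metal)] = 1.0
    additive = np.zeros(2)
    additive[1 if record.additive_present else 0] = 1.0
    conditions = np.array([record.temperature, record.pressure,
                           record.catalyst_loading], dtype=float)
    if condition_scaler is not None:
        conditions = condition_scaler.transform(conditions)
    vec = np.concatenate(parts + [metal, additive, conditions])
    assert vec.shape[0] == FEATURE_DIM
    return vec


def encode_reactions(records, condition_scaler: ConditionScaler | None = None,
                     threshold: float = 80.0):
    """Encode a list of records into (X, y).

    Returns the (n, 1544) feature matrix and the binary high-ee labels.
    """
    X = np.stack([encode_reaction(r, condition_scaler) for r in records])
    y = np.array([binarize_ee(r.ee, threshold) for r in records], dtype=int)
    return X, y


def binarize_ee(ee: float, threshold: float = 80.0) -> int:
    """1 when %ee strictly exceeds the threshold, else 0."""
    if not (0.0 <= ee <= 100.0):
        raise FeaturizationError(f"ee={ee} outside [0, 100]")
    return int(ee > threshold)


def feature_layout() -> dict:
    """Slice layout of the encoded vector, for sidecar metadata."""
    return {
        "olefin_fp": [0, FP_BITS],
        "ligand_fp": [FP_BITS, 2 * FP_BITS],
        "solvent_fp": [2 * FP_BITS, 3 * FP_BITS],
        "metal_onehot": [3 * FP_BITS, 3 * FP_BITS + len(METALS)],
        "additive_onehot": [3 * FP_BITS + len(METALS), 3 * FP_BITS + len(METALS) + 2],
        "conditions": [FEATURE_DIM - 3, FEATURE_DIM],
        "metals": list(METALS),
        "fp_bits": FP_BITS,
        "fp_radius": FP_RADIUS,
        "dim": FEATURE_DIM,
    }
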