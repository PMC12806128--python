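"""Text-based perturbation representation and the fingerprint baseline.

A chemical perturbation is represented as free text: a molecule description
followed by a dose prompt ("The dosage is <x> micromoles"), encoded into a
token matrix ``(n_token, d_text)``.  Production pipelines plug in external
describer/encoder models through :class:`PerturbationEmbedder`; the built-in
backends are a deterministic describer derived from the canonical SMILES and a
seeded hash encoder, so the whole path runs offline and reproducibly.  The
alternative baseline representation is an FCFP4 circular fingerprint weighted
by the log10-scaled dose.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; invalid SMILES raise below

__all__ = [
    "InvalidSMILESError",
    "canonical_smiles",
    "describe_molecule",
    "build_dose_prompt",
    "format_dose",
    "TextEmbedding",
    "FingerprintEmbedding",
    "HashTextEncoder",
    "pool_embedding",
    "fingerprint_embedding",
    "PerturbationEmbedder",
    "EmbeddingCache",
]


class InvalidSMILESError(ValueError):
    """Raised when a SMILES string cannot be canonicalized."""


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES; this canonical form also serves as the drug identity."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidSMILESError(f"invalid SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSMILESError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def is_valid_smiles(smiles) -> bool:
    try:
        canonical_smiles(smiles)
        return True
    except InvalidSMILESError:
        return False


def describe_molecule(smiles: str, describer=None) -> str:
    """Turn a SMILES into a molecule description sentence.

    ``describer`` may be any callable ``canonical_smiles -> str`` (e.g. a
    wrapper around an external molecule-captioning model).  The built-in
    default derives a deterministic sentence from cheminformatics descriptors,
    so two spellings of one molecule always yield the same text.
    """
    can = canonical_smiles(smiles)
    if describer is not None:
        text = describer(can)
        if not text:
            raise ValueError("describer returned empty text")
        return text
    mol = Chem.MolFromSmiles(can)
    formula = rdMolDescriptors.CalcMolFormula(mol)
    n_heavy = mol.GetNumHeavyAtoms()
    n_rings = rdMolDescriptors.CalcNumRings(mol)
    mw = Descriptors.MolWt(mol)
    return f"Molecule {can} formula {formula} atoms {n_heavy} rings {n_rings} weight {mw:.1f}."


def format_dose(dose_um: float) -> str:
    """Plain-decimal dose with trailing zeros stripped (10.0 -> "10")."""
    return np.format_float_positional(float(dose_um), trim="-")


def build_dose_prompt(description: str, dose_um: float) -> str:
    """Append the dose sentence to a molecule description."""
    if not description:
        raise ValueError("description must be non-empty")
    dose_um = float(dose_um)
    if dose_um <= 0:
        raise ValueError(f"dose must be positive, got {dose_um}")
    return f"{description} The dosage is {format_dose(dose_um)} micromoles"


@dataclass
class TextEmbedding:
    """Token matrix ``(n_token, d_text)`` with a padding mask.

    ``tokens`` is padded/truncated to the encoder's ``max_tokens``; ``mask``
    marks real tokens.  ``pooled`` (when present) is the mean over real
    tokens — the vector-like variant used by AdaLN-style conditioning.
    """

    tokens: np.ndarray
    mask: np.ndarray
    pooled: np.ndarray | None = None

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tokens.ndim != 2:
            raise ValueError("tokens must be 2-D (n_token, d_text)")
        if self.mask.shape != (self.tokens.shape[0],):
            raise ValueError("mask length must equal n_token")
        if not self.mask.any():
            raise ValueError("embedding must contain at least one real token")
        if not np.all(np.isfinite(self.tokens)):
            raise ValueError("token embedding contains non-finite values")

    @property
    def n_token(self) -> int:
        return int(self.mask.sum())

    @property
    def d_text(self) -> int:
        return self.tokens.shape[1]


@dataclass
class FingerprintEmbedding:
    """FCFP4 bit vector scaled by log10(dose)."""

    vector: np.ndarray

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("fingerprint embedding contains non-finite values")


def pool_embedding(emb: TextEmbedding) -> np.ndarray:
    """Arithmetic mean over the real (unmasked) tokens."""
    return emb.tokens[emb.mask].mean(axis=0)


class HashTextEncoder:
    """Deterministic per-token hash embedder.

    Each whitespace token maps to a fixed pseudo-random vector seeded by a
    keyed BLAKE2 digest of the token, so identical prompts give identical
    matrices across processes with no model download.  Not a semantic
    embedding — a plumbing-faithful stand-in exercising the same shapes,
    masking and determinism contracts as an external text encoder.
    """

    def __init__(self, d_text: int = 64, max_tokens: int = 32, seed: int = 0):
        if d_text < 1 or max_tokens < 1:
            raise ValueError("d_text and max_tokens must be >= 1")
        self.d_text = int(d_text)
        self.max_tokens = int(max_tokens)
        self.seed = int(seed)

    def _token_vector(self, token: str) -> np.ndarray:
        digest = hashlib.blake2b(
            token.encode("utf-8"), key=str(self.seed).encode(), digest_size=8
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        return rng.standard_normal(self.d_text)

    def encode_prompt(self, prompt: str) -> TextEmbedding:
        if not prompt or not prompt.strip():
            raise ValueError("prompt must be non-empty")
        words = prompt.split()[: self.max_tokens]
        tokens = np.zeros((self.max_tokens, self.d_text))
        mask = np.zeros(self.max_tokens, dtype=bool)
        for i, word in enumerate(words):
            tokens[i] = self._token_vector(word)
            mask[i] = True
        emb = TextEmbedding(tokens=tokens, mask=mask)
        emb.pooled = pool_embedding(emb)
        return emb


def embed_text(prompt: str, encoder: HashTextEncoder | None = None) -> TextEmbedding:
    """Encode a prompt into a token matrix with the given (or default) encoder."""
    return (encoder or HashTextEncoder()).encode_prompt(prompt)


_FP_GENERATORS: dict[int, object] = {}


def fingerprint_embedding(smiles: str, dose_um: float, n_bits: int = 1024) -> FingerprintEmbedding:
    """FCFP4 (feature-based Morgan, radius 2) bits weighted by log10(dose).

    Note dose_um = 1 gives weight log10(1) = 0 and hence a zero vector; this
    reproduces the stated baseline weighting and is warned about rather than
    special-cased.
    """
    can = canonical_smiles(smiles)
    dose_um = float(dose_um)
    if dose_um <= 0:
        raise ValueError(f"dose must be positive, got {dose_um}")
    gen = _FP_GENERATORS.get(n_bits)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=2,
            fpSize=n_bits,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
        )
        _FP_GENERATORS[n_bits] = gen
    bits = np.array(gen.GetFingerprint(Chem.MolFromSmiles(can)), dtype=np.float64)
    weight = np.log10(dose_um)
    if weight == 0.0:
        warnings.warn(
            "dose 1 micromole gives log10 weight 0: fingerprint embedding is the zero vector",
            stacklevel=2,
        )
    return FingerprintEmbedding(vector=bits * weight)


class EmbeddingCache:
    """Precomputed token embeddings keyed by (canonical SMILES, dose).

    Persisted as an HDF5 file with one dataset per key plus a JSON manifest
    mapping keys to dataset names, so embeddings computed once by an external
    encoder can be reused offline.
    """

    def __init__(self):
        self._store: dict[tuple[str, str], TextEmbedding] = {}

    @staticmethod
    def _key(smiles: str, dose_um: float) -> tuple[str, str]:
        return canonical_smiles(smiles), format_dose(dose_um)

    def put(self, smiles: str, dose_um: float, emb: TextEmbedding) -> None:
        self._store[self._key(smiles, dose_um)] = emb

    def get(self, smiles: str, dose_um: float) -> TextEmbedding:
        key = self._key(smiles, dose_um)
        if key not in self._store:
            raise KeyError(f"no cached embedding for SMILES={key[0]!r} dose={key[1]}")
        return self._store[key]

    def __contains__(self, key: tuple[str, float]) -> bool:
        return self._key(*key) in self._store

    def __len__(self) -> int:
        return len(self._store)

    def save(self, h5_path, manifest_path) -> None:
        import h5py

        manifest = []
        with h5py.File(h5_path, "w") as f:
            for i, ((smi, dose), emb) in enumerate(sorted(self._store.items())):
                name = f"emb_{i:06d}"
                grp = f.create_group(name)
                grp.create_dataset("tokens", data=emb.tokens)
                grp.create_dataset("mask", data=emb.mask)
                manifest.append({"smiles": smi, "dose": dose, "dataset": name})
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, h5_path, manifest_path) -> "EmbeddingCache":
        import h5py

        cache = cls()
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        with h5py.File(h5_path, "r") as f:
            for entry in manifest:
                grp = f[entry["dataset"]]
                emb = TextEmbedding(tokens=grp["tokens"][...], mask=grp["mask"][...])
                emb.pooled = pool_embedding(emb)
                cache._store[(entry["smiles"], entry["dose"])] = emb
        return cache


@dataclass
class PerturbationEmbedder:
    """End-to-end map (SMILES, dose) -> TextEmbedding.

    Backends, tried in order:

    1. ``cache`` — precomputed embeddings (e.g. from external description and
       text-encoder models) keyed by canonical SMILES and dose;
    2. the describe -> dose-prompt -> encode path using ``describer`` (or the
       built-in deterministic describer) and ``encoder`` (default
       :class:`HashTextEncoder`).

    The composite is a pure function of (canonical SMILES, dose).
    """

    encoder: HashTextEncoder | None = field(default_factory=HashTextEncoder)
    describer: object = None
    cache: EmbeddingCache | None = None

    def embed(self, smiles: str, dose_um: float) -> TextEmbedding:
        if self.cache is not None:
            try:
                return self.cache.get(smiles, dose_um)
            except KeyError:
                if self.encoder is None:
                    raise
        if self.encoder is None:
            raise KeyError(
                f"no cached embedding for (smiles={smiles!r}, dose={format_dose(dose_um)}) "
                "and no encoder configured"
            )
        description = describe_molecule(smiles, describer=self.describer)
        prompt = build_dose_prompt(description, dose_um)
        return self.encoder.encode_prompt(prompt)
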