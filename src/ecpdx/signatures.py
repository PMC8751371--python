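"""96-channel mutation catalogs and COSMIC-v2-style signature refitting.

The refit follows the deconstructSigs recipe: forward selection of
signatures by one-dimensional line search on the weight simplex, a minimum
per-signature contribution cut-off (15% by default), and a final
nonnegative least-squares refit restricted to the surviving signatures.
A dominance rule (>=30% of mutations attributed to one signature) maps the
top exposure to an etiology label (age, APOBEC, HRD, MMR, POLE, POLE+MMR).

The bundled signature matrix is SYNTHETIC: a deterministic 30-signature
stand-in with the canonical COSMIC v2 names and etiologies.  Signatures the
analysis depends on (1, 2, 3, 5, 6, 10, 13, 14, 15, 20, 26) carry their
literature-described peak structure (e.g. Signature 1 = C>T at NpCpG,
Signature 2/13 = APOBEC C>T / C>G at TpCpN, Signature 3 = featureless/flat,
Signature 10 = POLE C>A at TpCpT); the remainder are seeded random spectra.
It is not the published COSMIC matrix and exposures computed against it are
only comparable within this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .core import SomaticVariant, revcomp

__all__ = [
    "SUBSTITUTIONS",
    "CONTEXTS",
    "CHANNELS",
    "channel_index",
    "MutationCatalog96",
    "SignatureCatalog",
    "ExposureEstimate",
    "synthetic_cosmic_v2_like_catalog",
    "build_catalog",
    "refit_exposures",
    "dominant_etiology",
    "ETIOLOGY_MAP",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
CONTEXTS = tuple(l + r for l in _BASES for r in _BASES)  # lexicographic 5'/3'
CHANNELS = tuple(
    f"{ctx[0]}[{sub}]{ctx[1]}" for sub in SUBSTITUTIONS for ctx in CONTEXTS
)

_CHANNEL_IDX = {ch: i for i, ch in enumerate(CHANNELS)}


def channel_index(sub: str, context3: str) -> int:
    """Index of (substitution, pyrimidine trinucleotide context) in the 96-vector."""
    return _CHANNEL_IDX[f"{context3[0]}[{sub}]{context3[2]}"]


@dataclass
class MutationCatalog96:
    """96-channel trinucleotide-context substitution counts."""

    counts: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("catalog must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("channel counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def spectrum(self) -> np.ndarray:
        """Channel fractions; raises on an empty catalog."""
        if self.total == 0:
            raise ValueError("empty spectrum")
        return self.counts / self.total


ETIOLOGY_MAP = {
    "Signature.1": "age",
    "Signature.5": "age",
    "Signature.2": "APOBEC",
    "Signature.13": "APOBEC",
    "Signature.3": "HRD",
    "Signature.6": "MMR",
    "Signature.15": "MMR",
    "Signature.20": "MMR",
    "Signature.26": "MMR",
    "Signature.10": "POLE",
    "Signature.14": "POLE+MMR",
}


@dataclass
class SignatureCatalog:
    """Named 96-channel signature probability vectors plus etiology labels."""

    names: tuple[str, ...]
    matrix: np.ndarray  # shape (n_signatures, 96), rows sum to 1
    etiology: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.names), 96):
            raise ValueError("matrix shape must be (n_signatures, 96)")
        if (self.matrix < 0).any():
            raise ValueError("signature entries must be nonnegative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each signature vector must sum to 1")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]

    def subset(self, names: list[str]) -> "SignatureCatalog":
        idx = [self.names.index(n) for n in names]
        return SignatureCatalog(
            names=tuple(names),
            matrix=self.matrix[idx],
            etiology={n: self.etiology.get(n, "other") for n in names},
        )


def _sub_slice(sub: str) -> slice:
    i = SUBSTITUTIONS.index(sub)
    return slice(16 * i, 16 * (i + 1))


def _peak(vec: np.ndarray, sub: str, weight: float, left: str = "ACGT",
          right: str = "ACGT") -> None:
    """Spread ``weight`` uniformly over the channels of ``sub`` whose flanking
    bases fall in the given sets."""
    idx = [
        16 * SUBSTITUTIONS.index(sub) + 4 * _BASES.index(l) + _BASES.index(r)
        for l in left
        for r in right
    ]
    vec[idx] += weight / len(idx)


def _shaped(spec: list[tuple[str, float, str, str]], floor: float) -> np.ndarray:
    v = np.full(96, floor / 96.0)
    for sub, w, left, right in spec:
        _peak(v, sub, w, left, right)
    return v / v.sum()


def synthetic_cosmic_v2_like_catalog() -> SignatureCatalog:
    """Deterministic synthetic 30-signature matrix (see module docstring).

    Named signatures follow their literature-described channel structure;
    the rest are Dirichlet draws from fixed seeds so the full matrix has the
    size and diversity of the COSMIC v2 set.
    """
    shaped: dict[int, np.ndarray] = {
        1: _shaped([("C>T", 0.75, "ACGT", "G"), ("T>C", 0.05, "ACGT", "ACGT")], 0.20),
        2: _shaped([("C>T", 0.80, "T", "ACGT")], 0.20),
        3: np.full(96, 1.0 / 96.0),  # flat: the HRD signature is featureless
        5: _shaped([("T>C", 0.55, "ACGT", "ACGT"), ("C>T", 0.15, "ACGT", "ACGT")], 0.30),
        6: _shaped([("C>T", 0.60, "G", "ACGT"), ("C>T", 0.15, "ACGT", "A")], 0.25),
        10: _shaped([("C>A", 0.60, "T", "T"), ("C>T", 0.25, "T", "G")], 0.15),
        13: _shaped([("C>G", 0.80, "T", "ACGT")], 0.20),
        14: _shaped([("C>A", 0.45, "ACGT", "T"), ("C>T", 0.25, "G", "T")], 0.30),
        15: _shaped([("C>T", 0.55, "ACGT", "T"), ("C>G", 0.10, "T", "ACGT")], 0.35),
        20: _shaped([("C>T", 0.45, "G", "A"), ("T>A", 0.20, "C", "ACGT")], 0.35),
        26: _shaped([("T>C", 0.60, "A", "ACGT")], 0.40),
    }
    rows = []
    names = []
    for k in range(1, 31):
        names.append(f"Signature.{k}")
        if k in shaped:
            rows.append(shaped[k])
        else:
            rng = np.random.default_rng(97_000 + k)
            rows.append(rng.dirichlet(np.full(96, 0.25)))
    etiology = {n: ETIOLOGY_MAP.get(n, "other") for n in names}
    return SignatureCatalog(names=tuple(names), matrix=np.vstack(rows), etiology=etiology)


def build_catalog(variants: list[SomaticVariant]) -> MutationCatalog96:
    """Bin SNVs into the 96-channel catalog (pyrimidine-strand convention).

    Non-SNVs are ignored.  Purine-reference SNVs are reverse-complemented
    into the pyrimidine channel.  Variants whose context disagrees with
    their reference allele are skipped and counted in ``n_skipped``.
    """
    counts = np.zeros(96)
    skipped = 0
    for v in variants:
        if v.vclass != "SNP" or v.context3 is None:
            continue
        ref, alt, ctx = v.ref.upper(), v.alt.upper(), v.context3.upper()
        if ref in "GA":
            ref, alt, ctx = revcomp(ref), revcomp(alt), revcomp(ctx)
        if ctx[1] != ref or ref not in "CT":
            skipped += 1
            continue
        counts[channel_index(f"{ref}>{alt}", ctx)] += 1
    return MutationCatalog96(counts=counts, n_skipped=skipped)


@dataclass
class ExposureEstimate:
    """Refit result: retained signature weights (each >= cutoff, summing to 1)."""

    weights: dict[str, float]
    residual_sse: float
    n_snvs: int
    cutoff_used: float

    def weight(self, name: str) -> float:
        return self.weights.get(name, 0.0)

    @property
    def max_weight(self) -> float:
        return max(self.weights.values()) if self.weights else 0.0


def _forward_select(obs: np.ndarray, cat: SignatureCatalog,
                    rel_tol: float = 1e-3) -> np.ndarray:
    """Greedy simplex fit: repeatedly blend in the single signature whose
    optimal convex combination with the current reconstruction most reduces
    SSE.  Returns a weight vector over all catalog signatures (sums to 1).

    The 1-D line search new = (1-t)*recon + t*sig is an exact quadratic in t,
    solved in closed form and clipped to [0, 1].  Ties break by signature
    order (name order in the catalog), for determinism.
    """
    n = len(cat.names)
    w = np.zeros(n)
    # first pick: best single signature
    sse0 = ((cat.matrix - obs) ** 2).sum(axis=1)
    best = int(np.argmin(sse0))
    w[best] = 1.0
    recon = cat.matrix[best].copy()
    sse = float(sse0[best])
    for _ in range(200):
        diff = cat.matrix - recon  # (n, 96)
        denom = (diff ** 2).sum(axis=1)
        numer = diff @ (obs - recon)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, numer / denom, 0.0)
        t = np.clip(t, 0.0, 1.0)
        cand = recon[None, :] + t[:, None] * diff
        sses = ((cand - obs) ** 2).sum(axis=1)
        k = int(np.argmin(sses))
        new_sse = float(sses[k])
        if sse <= 0 or (sse - new_sse) / sse < rel_tol:
            break
        w *= 1.0 - t[k]
        w[k] += t[k]
        recon = cand[k]
        sse = new_sse
    return w


def refit_exposures(catalog: MutationCatalog96, signature_catalog: SignatureCatalog,
                    cutoff: float = 0.15) -> ExposureEstimate:
    """Estimate signature exposures for one catalog.

    Stage 1: forward selection on the weight simplex (greedy line search,
    stopping when the relative SSE improvement falls below 1e-3).
    Stage 2: drop signatures with weight below ``cutoff``.
    Stage 3: nonnegative least squares restricted to the survivors,
    renormalized to sum to 1.
    """
    obs = catalog.spectrum()
    w = _forward_select(obs, signature_catalog)
    keep = [i for i in range(len(w)) if w[i] >= cutoff]
    if not keep:
        keep = [int(np.argmax(w))]
    sub = signature_catalog.matrix[keep]
    coef, _ = nnls(sub.T, obs)
    if coef.sum() <= 0:
        coef = w[keep]
    coef = coef / coef.sum()
    # the NNLS refit can push a survivor back under the cutoff; re-drop once
    final = [(i, c) for i, c in zip(keep, coef) if c >= cutoff]
    if final and len(final) < len(keep):
        keep = [i for i, _ in final]
        sub = signature_catalog.matrix[keep]
        coef, _ = nnls(sub.T, obs)
        coef = coef / coef.sum()
    recon = coef @ sub
    sse = float(((recon - obs) ** 2).sum())
    weights = {signature_catalog.names[i]: float(c) for i, c in zip(keep, coef)}
    return ExposureEstimate(
        weights=weights,
        residual_sse=sse,
        n_snvs=int(round(catalog.total)),
        cutoff_used=cutoff,
    )


def dominant_etiology(exposure: ExposureEstimate,
                      signature_catalog: SignatureCatalog | None = None,
                      threshold: float = 0.30) -> str | None:
    """Etiology of the top-weight signature if it reaches ``threshold``,
    else None (no dominant signature)."""
    if not exposure.weights:
        return None
    name = max(sorted(exposure.weights), key=lambda n: exposure.weights[n])
    if exposure.weights[name] < threshold:
        return None
    if signature_catalog is not None:
        return signature_catalog.etiology.get(name, "other")
    return ETIOLOGY_MAP.get(name, "other")
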