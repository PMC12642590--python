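"""Per-residue feature assembly for variant effect models.

Every variant is encoded as an ``L x D`` real matrix, one row per residue of
the reference protein.  The row layout is a fixed block structure:

====================  =====  ==========================================
block                 width  content
====================  =====  ==========================================
one-hot               21     indicator over 20 canonical residues + stop
amino-acid PCs        19     principal components of a physicochemical
                             property matrix, min-max scaled to [0, 1]
energy terms          8      total folding ddG plus the 7 highest-variance
                             per-term components, tanh-squashed above
                             50 REU and min-max scaled (biophysics only)
RMSF                  1      per-residue C-alpha flexibility, min-max
                             scaled (biophysics only)
====================  =====  ==========================================

giving D = 40 without the biophysics blocks and D = 49 with them.

The energy resource is a precomputed table of mutational folding
free-energy changes (ddG = dG_wildtype - dG_mutant, in Rosetta energy
units) for every (site, substitution) pair including the wild-type
self-substitution, produced externally by a side-chain repacking protocol
(repacking radius 12 A, one repacking iteration by default).  Multi-mutant
variants place each constituent mutation's single-mutation energy row at
its own position; additivity across sites is left to the downstream model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dms_data import ALPHABET, CANONICAL_AA, DMSDataset, Variant

AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
CANONICAL_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

SQUASH_THRESHOLD = 50.0  # REU; larger energies come from steric clashes
N_AAINDEX_PCS = 19
N_ENERGY_TERMS = 7  # components kept besides the total ddG


def squash_energy(value, threshold: float = SQUASH_THRESHOLD):
    """Saturate unphysically large energies above a threshold.

    Identity below the threshold; above it the excess is passed through a
    tanh so the output approaches ``2 * threshold`` asymptotically:

        f(x) = x                                        x <= t
        f(x) = t + t * tanh((x - t) / t)                x > t

    The form is continuous with unit slope at the threshold.  Accepts
    scalars or arrays.
    """
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("squash_energy requires finite input")
    out = np.where(
        arr <= threshold,
        arr,
        threshold + threshold * np.tanh((arr - threshold) / threshold),
    )
    return float(out) if np.isscalar(value) else out


@dataclass
class EnergyTable:
    """Per-site, per-substitution mutational energy terms.

    ``totals[i, a]`` is the total ddG (REU) for substituting canonical amino
    acid ``CANONICAL_AA[a]`` at position ``i + 1``; ``terms[i, a, t]`` are the
    per-term components named by ``term_names``.  Self-substitutions are
    present (near-zero ddG by construction of the protocol).
    """

    term_names: list[str]
    totals: np.ndarray  # (L, 20)
    terms: np.ndarray  # (L, 20, T)
    protocol: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = self.totals.shape[0]
        if self.totals.shape != (L, 20):
            raise ValueError(f"totals must be (L, 20), got {self.totals.shape}")
        if self.terms.shape != (L, 20, len(self.term_names)):
            raise ValueError(
                f"terms must be (L, 20, {len(self.term_names)}), got {self.terms.shape}"
            )

    @property
    def length(self) -> int:
        return self.totals.shape[0]

    def entry(self, position: int, aa: str) -> tuple[float, np.ndarray]:
        """(total ddG, term vector) for a 1-based position and substitution."""
        a = CANONICAL_INDEX[aa]
        return float(self.totals[position - 1, a]), self.terms[position - 1, a]


def read_energy_table(path: str | Path) -> EnergyTable:
    """Read the TSV exchange form of an energy table.

    Columns: position, wt_aa, mut_aa, ddg_total, then one column per term.
    Protocol metadata may appear in ``# key=value`` header comments.
    """
    path = Path(path)
    protocol: dict = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            for token in line[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    try:
                        protocol[k] = float(v) if "." in v else int(v)
                    except ValueError:
                        protocol[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    required = {"position", "wt_aa", "mut_aa", "ddg_total"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    term_names = [c for c in df.columns if c not in required]
    L = int(df["position"].max())
    totals = np.full((L, 20), np.nan)
    terms = np.full((L, 20, len(term_names)), np.nan)
    rows = df["position"].to_numpy(int) - 1
    cols = np.array([CANONICAL_INDEX[a] for a in df["mut_aa"]])
    totals[rows, cols] = df["ddg_total"].to_numpy(float)
    terms[rows, cols] = df[term_names].to_numpy(float)
    if np.isnan(totals).any():
        missing = int(np.isnan(totals).sum())
        raise ValueError(f"{path}: {missing} (position, substitution) entries missing")
    return EnergyTable(term_names, totals, terms, protocol)


def write_energy_table(table: EnergyTable, path: str | Path, reference: str) -> None:
    with Path(path).open("w") as fh:
        if table.protocol:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in table.protocol.items()) + "\n")
        fh.write("position\twt_aa\tmut_aa\tddg_total\t" + "\t".join(table.term_names) + "\n")
        for i in range(table.length):
            for a, aa in enumerate(CANONICAL_AA):
                vals = "\t".join(repr(float(x)) for x in table.terms[i, a])
                fh.write(
                    f"{i + 1}\t{reference[i]}\t{aa}\t{float(table.totals[i, a])!r}\t{vals}\n"
                )


def select_energy_terms(table: EnergyTable, k: int = N_ENERGY_TERMS) -> list[str]:
    """Pick the ``k`` component terms with the largest variance.

    Variance is computed over all (position, substitution) entries after
    squashing.  The total ddG is not a candidate here: it is always kept as
    its own feature, so with the default ``k = 7`` the encoder ends up with
    8 energy features.  Ties break by term label, lexicographically.
    """
    if k > len(table.term_names):
        raise ValueError(f"k={k} exceeds the {len(table.term_names)} available terms")
    squashed = squash_energy(table.terms.reshape(-1, len(table.term_names)))
    variances = squashed.var(axis=0)
    order = sorted(range(len(table.term_names)), key=lambda t: (-variances[t], table.term_names[t]))
    return [table.term_names[t] for t in order[:k]]


class MinMaxNormalizer:
    """Affine map sending an observed range to [0, 1], clipping outside it.

    Fitted on the resource or training values only; unseen values beyond
    the fitted range are clipped rather than extrapolated.
    """

    def __init__(self, minimum: float, maximum: float):
        if not maximum > minimum:
            raise ValueError(
                "degenerate (constant) feature: min == max; exclude this feature "
                "instead of normalizing it"
            )
        self.minimum = float(minimum)
        self.maximum = float(maximum)

    @classmethod
    def fit(cls, values) -> "MinMaxNormalizer":
        arr = np.asarray(values, dtype=float)
        return cls(arr.min(), arr.max())

    def apply(self, value):
        arr = (np.asarray(value, dtype=float) - self.minimum) / (
            self.maximum - self.minimum
        )
        out = np.clip(arr, 0.0, 1.0)
        return float(out) if np.isscalar(value) else out


@dataclass
class AAIndexPCs:
    """Principal-component scores of an amino-acid property matrix.

    ``components[a, j]`` is the j-th PC score of canonical amino acid
    ``CANONICAL_AA[a]``, min-max scaled so every column spans [0, 1].
    """

    components: np.ndarray  # (20, K)

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def compute_aaindex_pcs(property_matrix: np.ndarray, K: int = N_AAINDEX_PCS) -> AAIndexPCs:
    """PCA-compress a 20 x P physicochemical property matrix.

    Twenty centered samples span at most a 19-dimensional space, so 19
    components always carry 100% of the variance.  Raises if the matrix
    rank (after centering) cannot support ``K`` components.
    """
    X = np.asarray(property_matrix, dtype=float)
    if X.shape[0] != 20:
        raise ValueError(f"expected 20 amino-acid rows, got {X.shape[0]}")
    if np.isnan(X).any():
        raise ValueError("property matrix has missing entries")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < K:
        raise ValueError(f"property matrix supports only {rank} components, need {K}")
    scores = PCA(n_components=K, svd_solver="full").fit_transform(X)
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    return AAIndexPCs((scores - lo) / (hi - lo))


def explained_variance_components(property_matrix: np.ndarray, tol: float = 1e-10) -> int:
    """Number of principal components carrying all (non-negligible) variance."""
    X = np.asarray(property_matrix, dtype=float)
    var = PCA(svd_solver="full").fit(X).explained_variance_ratio_
    return int(np.sum(var > tol))


@dataclass
class RMSFProfile:
    """Per-residue C-alpha root-mean-square fluctuation (A)."""

    values: np.ndarray  # (L,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("RMSF values must be non-negative")

    @property
    def length(self) -> int:
        return len(self.values)


def read_rmsf_profile(path: str | Path) -> RMSFProfile:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("position")
    return RMSFProfile(df["rmsf"].to_numpy(float))


def write_rmsf_profile(profile: RMSFProfile, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("position\trmsf\n")
        for i, v in enumerate(profile.values, start=1):
            fh.write(f"{i}\t{float(v)!r}\n")


ONEHOT_DIM = len(ALPHABET)  # 21
DIM_WITHOUT_BIOPHYSICS = ONEHOT_DIM + N_AAINDEX_PCS  # 40
DIM_WITH_BIOPHYSICS = DIM_WITHOUT_BIOPHYSICS + 1 + N_ENERGY_TERMS + 1  # 49


@dataclass
class FeatureResources:
    """Fitted, reference-consistent resources needed to encode variants.

    Built once per protein with :func:`fit_feature_resources`; the fitted
    min-max normalizers travel with the resources so that train and test
    variants are scaled identically.
    """

    reference: str
    aaindex: AAIndexPCs
    energy_table: EnergyTable | None = None
    selected_terms: list[str] | None = None
    rmsf: RMSFProfile | None = None
    energy_normalizers: list[MinMaxNormalizer] | None = None
    ddg_normalizer: MinMaxNormalizer | None = None
    rmsf_normalizer: MinMaxNormalizer | None = None
    # cached (L, 20, 8) normalized energy block + (L,) normalized rmsf
    _energy_block: np.ndarray | None = None
    _rmsf_norm: np.ndarray | None = None

    @property
    def has_biophysics(self) -> bool:
        return self.energy_table is not None and self.rmsf is not None

    def fingerprint(self) -> dict:
        """Compact identity of the resources a model was trained with."""
        return {
            "reference_length": len(self.reference),
            "with_biophysics": self.has_biophysics,
            "selected_terms": self.selected_terms,
            "n_aaindex_pcs": self.aaindex.n_components,
        }


def fit_feature_resources(
    reference: str,
    aaindex_properties: np.ndarray,
    energy_table: EnergyTable | None = None,
    rmsf: RMSFProfile | None = None,
    *,
    n_terms: int = N_ENERGY_TERMS,
    n_pcs: int = N_AAINDEX_PCS,
) -> FeatureResources:
    """Fit PCA, term selection, and min-max normalizers for one protein.

    The energy and RMSF normalizers are fitted over the full (variant-
    independent) resource tables, which depend only on the wild-type
    protein, never on which variants end up in a training split.
    """
    aaindex = compute_aaindex_pcs(aaindex_properties, K=n_pcs)
    res = FeatureResources(reference=reference, aaindex=aaindex)
    if energy_table is None:
        return res
    if energy_table.length != len(reference):
        raise ValueError(
            f"energy table covers {energy_table.length} positions, reference has "
            f"{len(reference)}"
        )
    if rmsf is None or rmsf.length != len(reference):
        raise ValueError("biophysics encoding needs an RMSF profile of matching length")
    selected = select_energy_terms(energy_table, k=n_terms)
    idx = [energy_table.term_names.index(t) for t in selected]
    sq_terms = squash_energy(energy_table.terms[:, :, idx])
    sq_total = squash_energy(energy_table.totals)
    ddg_norm = MinMaxNormalizer.fit(sq_total)
    term_norms = [MinMaxNormalizer.fit(sq_terms[:, :, j]) for j in range(len(idx))]
    block = np.empty((energy_table.length, 20, 1 + len(idx)))
    block[:, :, 0] = ddg_norm.apply(sq_total)
    for j, nm in enumerate(term_norms):
        block[:, :, 1 + j] = nm.apply(sq_terms[:, :, j])
    rmsf_norm = MinMaxNormalizer.fit(rmsf.values)
    res.energy_table = energy_table
    res.selected_terms = selected
    res.rmsf = rmsf
    res.energy_normalizers = term_norms
    res.ddg_normalizer = ddg_norm
    res.rmsf_normalizer = rmsf_norm
    res._energy_block = block
    res._rmsf_norm = rmsf_norm.apply(rmsf.values)
    return res


def encode_variant(
    variant: Variant,
    resources: FeatureResources,
    with_biophysics: bool = True,
) -> np.ndarray:
    """Encode one variant as an ``L x D`` feature matrix.

    Row ``i`` describes the amino acid present at position ``i + 1`` of the
    variant sequence: its one-hot indicator and property PCs, plus (when
    biophysics is enabled) the normalized energy entry of the substitution
    at that position and the residue's normalized flexibility.  Unmutated
    rows carry the wild-type self-substitution energy entry; stop-codon
    rows use the saturating fallback (all energy features at the squash
    ceiling — a truncation is maximally destabilizing) and zero property
    PCs, since physicochemical properties are only defined for residues.
    """
    ref = resources.reference
    L = len(ref)
    if with_biophysics and not resources.has_biophysics:
        raise ValueError("resources were fitted without energy/RMSF inputs")
    D = DIM_WITH_BIOPHYSICS if with_biophysics else DIM_WITHOUT_BIOPHYSICS
    X = np.zeros((L, D))
    seq = variant.apply(ref)
    aa_rows = np.array([AA_INDEX[a] for a in seq])
    X[np.arange(L), aa_rows] = 1.0  # one-hot block
    canonical = aa_rows < 20
    X[canonical, ONEHOT_DIM : ONEHOT_DIM + N_AAINDEX_PCS] = resources.aaindex.components[
        aa_rows[canonical]
    ]
    if not with_biophysics:
        return X
    e0 = ONEHOT_DIM + N_AAINDEX_PCS
    block = resources._energy_block
    # wild-type rows use the self-substitution entry; stop rows the ceiling
    X[canonical, e0 : e0 + 1 + N_ENERGY_TERMS] = block[
        np.arange(L)[canonical], aa_rows[canonical]
    ]
    X[~canonical, e0 : e0 + 1 + N_ENERGY_TERMS] = 1.0
    X[:, -1] = resources._rmsf_norm
    return X


def encode_dataset(
    dataset: DMSDataset,
    resources: FeatureResources,
    with_biophysics: bool = True,
) -> np.ndarray:
    """Stack variant encodings into an ``(N, L, D)`` array."""
    return np.stack(
        [encode_variant(v, resources, with_biophysics) for v in dataset.variants]
    )
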