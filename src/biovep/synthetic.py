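"""Self-consistent synthetic fixtures for the whole pipeline.

Generates a complete artificial protein "world": a reference sequence, an
idealized helical structure, a per-site x per-substitution energy table, a
flexibility profile, an amino-acid property matrix, and DMS datasets with
sequencing read counts — all deterministic functions of a seed.

The central design choice is that ground-truth fitness depends on sequence
*only through the energy table*: a variant's fitness is a logistic function
of its summed total ddG (a two-state stability-fitness curve), so the
biophysics features are sufficient statistics for fitness.  Models with
access to them can in principle extrapolate to unseen positions, while
sequence-only models cannot (the per-site energies are independent draws,
so amino-acid identity carries no cross-position signal).  This makes the
world a controlled test-bed for the extrapolation experiments.

Selection is modeled as exponential amplification: a variant's frequency
in the post-selection pool is proportional to its input frequency times
``exp(alpha * fitness)``, and both pools are sequenced as multinomial
draws, which is exactly the generative model the enrichment score inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.PDB import PDBIO, StructureBuilder

from .dms_data import CANONICAL_AA, DMSDataset, Mutation, Variant
from .features import (
    EnergyTable,
    RMSFProfile,
    write_energy_table,
    write_rmsf_profile,
)
from .structure import ResidueCoordinates

# REF2015-style energy term labels; the exact identities only matter for
# realism of the exchange format.
TERM_NAMES = [
    "fa_atr", "fa_rep", "fa_sol", "fa_intra_rep", "fa_intra_sol_xover4",
    "lk_ball_wtd", "fa_elec", "pro_close", "hbond_sr_bb", "hbond_lr_bb",
    "hbond_bb_sc", "hbond_sc", "dslf_fa13", "omega", "fa_dun",
    "p_aa_pp", "yhh_planarity", "ref", "rama_prepro",
]

CLASH_TERM = "fa_rep"  # steric clashes produce the > 50 REU outliers
STOP_DDG = 100.0  # squash ceiling: a truncation is maximally destabilizing


@dataclass
class FitnessParams:
    """Two-state logistic stability-fitness link.

    ``fitness = max_score / (1 + exp((sum_ddG - midpoint) / softness))``:
    variants whose cumulative destabilization crosses ``midpoint`` (REU)
    lose function over a transition of width ``softness``.
    """

    midpoint: float = 5.0
    softness: float = 2.0
    max_score: float = 1.0
    noise_sd: float = 0.02


@dataclass
class SyntheticWorld:
    reference: str
    ca_coords: np.ndarray  # (L, 3)
    cb_coords: np.ndarray  # (L, 3); row equals ca for glycine
    energy_table: EnergyTable
    rmsf: RMSFProfile
    aaindex_properties: np.ndarray  # (20, P)
    fitness: FitnessParams = field(default_factory=FitnessParams)
    selection_strength: float = 4.0
    seed: int = 0

    @property
    def length(self) -> int:
        return len(self.reference)

    def representative_coords(self) -> ResidueCoordinates:
        coords = np.where(
            (np.array(list(self.reference)) == "G")[:, None],
            self.ca_coords,
            self.cb_coords,
        )
        return ResidueCoordinates(coords, self.reference)


def _helix_coords(L: int) -> tuple[np.ndarray, np.ndarray]:
    """Idealized alpha-helix C-alpha trace with radially offset C-betas."""
    t = np.arange(L)
    theta = np.deg2rad(100.0) * t
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros(L)], axis=1)
    ca = 2.3 * radial + np.stack([np.zeros(L), np.zeros(L), 1.5 * t], axis=1)
    cb = ca + 1.5 * radial
    return ca, cb


def generate_world(
    L: int = 50,
    n_terms: int = 19,
    seed: int = 0,
    *,
    n_properties: int = 60,
    clash_fraction: float = 0.015,
    fitness: FitnessParams | None = None,
    selection_strength: float = 4.0,
) -> SyntheticWorld:
    """Generate one synthetic protein world.

    Energy terms are independent normals with a geometric ladder of
    per-term scales (so variance-based term selection has real structure
    to find); a small fraction of entries receive a large steric-clash
    penalty on the repulsive term, exceeding the 50 REU squash threshold.
    Self-substitutions are exactly zero in every term, and the total ddG
    is the sum of the components.
    """
    if L < 10:
        raise ValueError(f"need L >= 10, got {L}")
    rng = np.random.default_rng(seed)
    reference = "".join(rng.choice(list(CANONICAL_AA), size=L))
    ca, cb = _helix_coords(L)

    term_names = list(TERM_NAMES[:n_terms])
    if len(term_names) < n_terms:
        term_names += [f"term_{i}" for i in range(len(term_names), n_terms)]
    scales = np.geomspace(0.05, 3.0, n_terms)
    rng.shuffle(scales)
    terms = rng.normal(0.0, 1.0, size=(L, 20, n_terms)) * scales
    clash_idx = term_names.index(CLASH_TERM) if CLASH_TERM in term_names else 0
    clashes = rng.random((L, 20)) < clash_fraction
    terms[:, :, clash_idx] += clashes * rng.uniform(55.0, 120.0, size=(L, 20))
    wt_idx = np.array([CANONICAL_AA.index(a) for a in reference])
    terms[np.arange(L), wt_idx, :] = 0.0  # self-substitution: no change
    totals = terms.sum(axis=2)
    table = EnergyTable(term_names, totals, terms, {"repack_radius": 12, "nloop": 1})

    # smooth positive flexibility profile, floppier toward the termini
    pos = np.arange(L) / max(L - 1, 1)
    rmsf_vals = (
        0.6
        + 0.8 * (np.exp(-pos / 0.08) + np.exp(-(1 - pos) / 0.08))
        + 0.25 * np.abs(np.sin(2.5 * np.pi * pos))
        + rng.uniform(0.0, 0.08, size=L)
    )
    # low-rank property matrix plus noise: correlated properties, full rank
    latent = rng.normal(size=(20, 6))
    loadings = rng.normal(size=(6, n_properties))
    props = latent @ loadings + 0.05 * rng.normal(size=(20, n_properties))

    return SyntheticWorld(
        reference=reference,
        ca_coords=ca,
        cb_coords=cb,
        energy_table=table,
        rmsf=RMSFProfile(rmsf_vals),
        aaindex_properties=props,
        fitness=fitness or FitnessParams(),
        selection_strength=selection_strength,
        seed=seed,
    )


def variant_ddg(world: SyntheticWorld, variant: Variant) -> float:
    """Summed total ddG of a variant, assuming additivity across sites."""
    total = 0.0
    for m in variant.mutations:
        if m.is_stop:
            total += STOP_DDG
        else:
            total += float(world.energy_table.totals[m.position - 1,
                                                     CANONICAL_AA.index(m.mut_aa)])
    return total


def true_fitness(world: SyntheticWorld, variant: Variant) -> float:
    """Noiseless ground-truth fitness of a variant (logistic in summed ddG)."""
    p = world.fitness
    z = (variant_ddg(world, variant) - p.midpoint) / p.softness
    return p.max_score / (1.0 + np.exp(z))


def sample_variants(
    world: SyntheticWorld,
    n_variants: int,
    mutation_count_probs: dict[int, float] | None = None,
    seed: int = 0,
) -> list[Variant]:
    """Draw unique random missense variants.

    The mutations-per-variant distribution defaults to 45% single, 40%
    double, 15% triple — the single/double-dominated shape typical of DMS
    libraries.  The wild type is always included as the first record (it
    anchors enrichment scoring).
    """
    probs = mutation_count_probs or {1: 0.45, 2: 0.40, 3: 0.15}
    ks = np.array(sorted(probs))
    pk = np.array([probs[k] for k in ks], dtype=float)
    pk = pk / pk.sum()
    rng = np.random.default_rng(seed)
    L = world.length
    seen: set[tuple] = set()
    variants: list[Variant] = [Variant()]
    attempts = 0
    while len(variants) < n_variants + 1 and attempts < 100 * n_variants:
        attempts += 1
        k = int(rng.choice(ks, p=pk))
        positions = rng.choice(L, size=k, replace=False) + 1
        muts = []
        for p in sorted(positions):
            wt = world.reference[p - 1]
            choices = [a for a in CANONICAL_AA if a != wt]
            muts.append(Mutation(int(p), wt, str(rng.choice(choices))))
        key = tuple((m.position, m.mut_aa) for m in muts)
        if key in seen:
            continue
        seen.add(key)
        variants.append(Variant(tuple(muts)))
    return variants


def generate_dms(
    world: SyntheticWorld,
    n_variants: int = 5000,
    mutation_count_probs: dict[int, float] | None = None,
    read_depth: int = 2_000_000,
    seed: int = 0,
    name: str = "synthetic",
) -> DMSDataset:
    """Simulate a counted, scored DMS dataset from the world.

    Input-pool frequencies are log-normal abundances; the selected pool
    reweights them by ``exp(alpha * fitness)`` where fitness carries the
    world's observation noise.  Both pools are sequenced to ``read_depth``
    total reads by multinomial draws, and scores are the wild-type-centered
    log2 enrichment of the resulting counts.
    """
    rng = np.random.default_rng(seed)
    variants = sample_variants(world, n_variants, mutation_count_probs, seed=seed)
    n = len(variants)
    abundance = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    p_input = abundance / abundance.sum()
    fit = np.array([true_fitness(world, v) for v in variants])
    fit = fit + rng.normal(0.0, world.fitness.noise_sd, size=n)
    w = p_input * np.exp(world.selection_strength * fit)
    p_selected = w / w.sum()
    c_in = rng.multinomial(read_depth, p_input)
    c_sel = rng.multinomial(read_depth, p_selected)
    counted = [
        Variant(v.mutations, count_input=int(ci), count_selected=int(cs))
        for v, ci, cs in zip(variants, c_in, c_sel)
    ]
    dataset = DMSDataset(world.reference, counted, name=name)
    return dataset.with_enrichment_scores()


def write_pdb(world: SyntheticWorld, path: str | Path) -> None:
    """Write the idealized structure (N/CA/CB backbone stub) as PDB."""
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("synt")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    for i, aa in enumerate(world.reference):
        resname = protein_letters_1to3[aa].upper()
        builder.init_residue(resname, " ", i + 1, " ")
        builder.init_atom("CA", world.ca_coords[i], 0.0, 1.0, " ", " CA ", element="C")
        if aa != "G":
            builder.init_atom("CB", world.cb_coords[i], 0.0, 1.0, " ", " CB ", element="C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def write_world(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write every fixture file in its standard exchange format."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "reference.fasta",
        "energy": directory / "energy_table.tsv",
        "rmsf": directory / "rmsf.tsv",
        "aaindex": directory / "aaindex_properties.tsv",
        "pdb": directory / "structure.pdb",
    }
    with paths["fasta"].open("w") as fh:
        fh.write(f">synthetic_world seed={world.seed}\n{world.reference}\n")
    write_energy_table(world.energy_table, paths["energy"], world.reference)
    write_rmsf_profile(world.rmsf, paths["rmsf"])
    with paths["aaindex"].open("w") as fh:
        P = world.aaindex_properties.shape[1]
        fh.write("aa\t" + "\t".join(f"prop_{j}" for j in range(P)) + "\n")
        for a, aa in enumerate(CANONICAL_AA):
            row = "\t".join(repr(float(x)) for x in world.aaindex_properties[a])
            fh.write(f"{aa}\t{row}\n")
    write_pdb(world, paths["pdb"])
    return paths
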