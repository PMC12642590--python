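"""Deep mutational scanning (DMS) variant datasets.

A DMS experiment measures a functional score for thousands of protein
variants by selecting a mutant library and sequencing the input and
post-selection pools.  This module defines the in-memory representation of
such datasets (mutations, variants, the dataset itself), parses and writes
the tab-separated tables they are exchanged in, and computes enrichment
scores from read counts.

Variant strings follow the common ``<wt><pos><mut>`` convention
(e.g. ``"E3K,L10P"``), 1-based against a reference sequence.  The amino
acid alphabet has 21 symbols: the 20 canonical residues plus ``*`` for a
stop codon.  Deletions and other indels are not representable and are
dropped (with a counted warning) at read time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
ALPHABET = CANONICAL_AA + STOP  # 21 symbols
WT_SENTINEL = "_wt"

_MUTATION_RE = re.compile(r"^([A-Z\*])(\d+)([A-Z\*])$")
_DELETION_RE = re.compile(r"del|ins|[A-Z]\d+-$|^-", re.IGNORECASE)


class VariantError(ValueError):
    """Raised when a variant string or record fails validation."""


@dataclass(frozen=True, order=True)
class Mutation:
    """A single point substitution, 1-based against the reference."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantError(f"position must be >= 1, got {self.position}")
        if self.wt_aa not in CANONICAL_AA:
            raise VariantError(f"unknown wild-type symbol {self.wt_aa!r}")
        if self.mut_aa not in ALPHABET:
            raise VariantError(f"unknown substitution symbol {self.mut_aa!r}")
        if self.mut_aa == self.wt_aa:
            raise VariantError(
                f"substitution equals wild type at position {self.position}"
            )

    @property
    def is_stop(self) -> bool:
        return self.mut_aa == STOP

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class Variant:
    """A set of point mutations with an optional score and read counts.

    An empty mutation tuple denotes the wild type.  Mutations are stored
    sorted by position so that equal variants compare equal regardless of
    the order the mutations were listed in.
    """

    mutations: tuple[Mutation, ...] = ()
    score: float | None = None
    count_input: int | None = None
    count_selected: int | None = None

    def __post_init__(self) -> None:
        muts = tuple(sorted(self.mutations))
        object.__setattr__(self, "mutations", muts)
        positions = [m.position for m in muts]
        if len(set(positions)) != len(positions):
            dup = next(p for p in positions if positions.count(p) > 1)
            raise VariantError(f"duplicate mutation at position {dup}")
        for name in ("count_input", "count_selected"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise VariantError(f"{name} must be non-negative, got {v}")

    @property
    def is_wildtype(self) -> bool:
        return not self.mutations

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    @property
    def has_stop(self) -> bool:
        return any(m.is_stop for m in self.mutations)

    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)

    def mutation_keys(self) -> frozenset[tuple[int, str]]:
        """Unique (position, substituted amino acid) pairs of this variant."""
        return frozenset((m.position, m.mut_aa) for m in self.mutations)

    def apply(self, reference: str) -> str:
        """Return the full-length mutant sequence."""
        seq = list(reference)
        for m in self.mutations:
            seq[m.position - 1] = m.mut_aa
        return "".join(seq)

    def __str__(self) -> str:
        return format_variant(self)


def format_variant(variant: Variant) -> str:
    """Serialize a variant to its comma-separated token form.

    The wild type formats to the ``"_wt"`` sentinel so that it survives a
    round trip through whitespace-stripping TSV tooling.
    """
    if variant.is_wildtype:
        return WT_SENTINEL
    return ",".join(str(m) for m in variant.mutations)


def parse_variant(
    text: str,
    reference: str,
    *,
    offset: int = 0,
    score: float | None = None,
    count_input: int | None = None,
    count_selected: int | None = None,
) -> Variant:
    """Parse a comma-separated mutation string against a reference sequence.

    Parameters
    ----------
    text:
        Tokens like ``"E3K"`` joined by commas; the empty string or the
        ``"_wt"`` sentinel denote the wild type.
    reference:
        The wild-type amino acid sequence the positions index into.
    offset:
        Added to each parsed position before validation, for tables whose
        numbering does not start at 1 (published DMS tables disagree on
        numbering conventions).

    Raises
    ------
    VariantError
        On a malformed token, an out-of-range position, a wild-type letter
        that disagrees with the reference, or a duplicated position.
    """
    text = text.strip()
    if text in ("", WT_SENTINEL):
        return Variant(
            (), score=score, count_input=count_input, count_selected=count_selected
        )
    mutations = []
    for token in text.split(","):
        token = token.strip()
        m = _MUTATION_RE.match(token)
        if m is None:
            raise VariantError(f"malformed mutation token {token!r}")
        wt, pos, mut = m.group(1), int(m.group(2)) + offset, m.group(3)
        if not 1 <= pos <= len(reference):
            raise VariantError(
                f"position {pos} outside reference of length {len(reference)}"
            )
        if reference[pos - 1] != wt:
            raise VariantError(
                f"token {token!r}: reference has {reference[pos - 1]!r} at "
                f"position {pos}, not {wt!r}"
            )
        mutations.append(Mutation(pos, wt, mut))
    return Variant(
        tuple(mutations),
        score=score,
        count_input=count_input,
        count_selected=count_selected,
    )


def enrichment_score(
    variant_counts: tuple[float, float],
    wt_counts: tuple[float, float],
    pseudocount: float = 0.5,
) -> float:
    """Wild-type-centered log2 enrichment of selected over input reads.

    Computes ``log2((c_sel+p)/(c_inp+p)) - log2((wt_sel+p)/(wt_inp+p))``,
    the two-condition ratio score with pseudocount ``p`` (the standard
    form for a two-timepoint selection with wild-type normalization).
    Positive scores mean the variant was enriched relative to wild type
    during selection.
    """
    c_inp, c_sel = variant_counts
    wt_inp, wt_sel = wt_counts
    for v in (c_inp, c_sel, wt_inp, wt_sel):
        if v < 0:
            raise ValueError(f"read counts must be non-negative, got {v}")
    return math.log2((c_sel + pseudocount) / (c_inp + pseudocount)) - math.log2(
        (wt_sel + pseudocount) / (wt_inp + pseudocount)
    )


@dataclass
class DMSDataset:
    """A reference sequence plus a list of scored variants."""

    reference_sequence: str
    variants: list[Variant]
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def scores(self) -> list[float | None]:
        return [v.score for v in self.variants]

    def wildtype(self) -> Variant | None:
        """The wild-type record, if the dataset contains one."""
        for v in self.variants:
            if v.is_wildtype:
                return v
        return None

    def with_enrichment_scores(self, pseudocount: float = 0.5) -> "DMSDataset":
        """Return a copy whose scores are recomputed from read counts.

        Requires a wild-type record with counts to center on.
        """
        wt = self.wildtype()
        if wt is None or wt.count_input is None or wt.count_selected is None:
            raise ValueError("dataset has no wild-type record with read counts")
        wt_counts = (wt.count_input, wt.count_selected)
        scored = []
        for v in self.variants:
            if v.count_input is None or v.count_selected is None:
                raise ValueError(f"variant {v} lacks read counts")
            s = enrichment_score((v.count_input, v.count_selected), wt_counts, pseudocount)
            scored.append(replace(v, score=s))
        return DMSDataset(self.reference_sequence, scored, name=self.name)


@dataclass
class DatasetSummary:
    n_variants: int
    n_unique_mutations: int
    coverage: float
    mutations_per_variant: dict[int, int] = field(default_factory=dict)


def dataset_summary(dataset: DMSDataset) -> DatasetSummary:
    """Summarize dataset size and mutational coverage.

    Coverage is the fraction of all possible missense substitutions
    (L positions x 19 non-identical canonical amino acids) observed at
    least once; stop substitutions do not count toward coverage.
    """
    unique: set[tuple[int, str]] = set()
    hist: dict[int, int] = {}
    for v in dataset.variants:
        unique.update(v.mutation_keys())
        hist[v.n_mutations] = hist.get(v.n_mutations, 0) + 1
    missense = {k for k in unique if k[1] != STOP}
    possible = len(dataset.reference_sequence) * 19
    coverage = len(missense) / possible if possible else 0.0
    return DatasetSummary(
        n_variants=len(dataset),
        n_unique_mutations=len(unique),
        coverage=coverage,
        mutations_per_variant=dict(sorted(hist.items())),
    )


def read_fasta(path: str | Path) -> str:
    """Read a single-record FASTA reference sequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    return str(records[0].seq)


def read_dms_table(
    path: str | Path,
    reference: str,
    *,
    name: str | None = None,
    offset: int = 0,
) -> tuple[DMSDataset, int]:
    """Read a tab-separated DMS table.

    The table must have a header with a ``variant`` column and at least one
    of ``score`` or both ``count_input`` and ``count_selected``.  Rows whose
    variant string encodes a deletion or insertion are excluded; the second
    return value counts the exclusions.  If scores are absent but counts are
    present, enrichment scores are computed on the fly.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            col = {c: i for i, c in enumerate(header)}
            i_var = col["variant"]
        except KeyError:
            raise ValueError(f"{path}: missing required 'variant' column") from None
        i_score = col.get("score")
        i_ci = col.get("count_input")
        i_cs = col.get("count_selected")
        if i_score is None and (i_ci is None or i_cs is None):
            raise ValueError(f"{path}: need a 'score' column or both count columns")

        variants: list[Variant] = []
        n_excluded = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            vtext = fields[i_var]
            if vtext not in ("", WT_SENTINEL) and _DELETION_RE.search(vtext):
                n_excluded += 1
                continue

            def _float(i):
                return float(fields[i]) if i is not None and fields[i] != "" else None

            def _int(i):
                return int(float(fields[i])) if i is not None and fields[i] != "" else None

            try:
                variant = parse_variant(
                    vtext,
                    reference,
                    offset=offset,
                    score=_float(i_score),
                    count_input=_int(i_ci),
                    count_selected=_int(i_cs),
                )
            except VariantError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            variants.append(variant)

    dataset = DMSDataset(reference, variants, name=name or path.stem)
    if i_score is None:
        dataset = dataset.with_enrichment_scores()
    return dataset, n_excluded


def write_dms_table(dataset: DMSDataset, path: str | Path) -> None:
    """Write a dataset back to its tab-separated form (lossless round trip)."""
    has_counts = any(v.count_input is not None for v in dataset.variants)
    has_scores = any(v.score is not None for v in dataset.variants)
    columns = ["variant"]
    if has_scores:
        columns.append("score")
    if has_counts:
        columns += ["count_input", "count_selected"]
    with Path(path).open("w") as fh:
        fh.write("\t".join(columns) + "\n")
        for v in dataset.variants:
            row = [format_variant(v)]
            if has_scores:
                row.append("" if v.score is None else repr(v.score))
            if has_counts:
                row.append("" if v.count_input is None else str(v.count_input))
                row.append("" if v.count_selected is None else str(v.count_selected))
            fh.write("\t".join(row) + "\n")


def unique_mutations(variants: Iterable[Variant]) -> set[tuple[int, str]]:
    """All unique (position, substitution) pairs across the given variants."""
    out: set[tuple[int, str]] = set()
    for v in variants:
        out.update(v.mutation_keys())
    return out


def mutated_positions(variants: Iterable[Variant]) -> set[int]:
    out: set[int] = set()
    for v in variants:
        out.update(v.positions())
    return out
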