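"""Seeded generators emulating the statistical structure of the study inputs.

Every generator takes an integer seed, is deterministic given (parameters,
seed), and returns its ground truth alongside the data so recovery tests can
compare analysis output against what was actually generated:

- expression tables: single-copy reference genes with log-normal
  interspecific variation around a shared baseline, plus focal genes
  fold-elevated in the glue species;
- modular PRIT-like proteins: signal peptide, ~390-residue structured
  domains, intervening arrays of 12-24 imperfect copies of an 18-mer unit
  carrying tandem PG motifs and Ser/Thr sites;
- disorder tracks high over repeats and low over domains;
- codon alignments evolved along a balanced tree with discrete omega site
  classes (nonsynonymous rates scaled by omega, transitions by kappa, stop
  codons forbidden);
- pull-test records with group means/SDs matching the published treatment
  summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats import CodonAlignmentSet, ExpressionTable, ResidueTrack, SequenceRecord
from .pulltest import BRICK_FACE_MM, PullTestRecord, rectangle_area_mm2
from .repeats import ArchitectureAnnotation, Segment
from .selection import CODON_TABLE, SENSE_CODONS, STOP_CODONS, _TRANSITIONS

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# 18-mer with two tandem PG dipeptides and three Ser/Thr sites, mirroring the
# described repeat unit of the Dyscophus glue protein
DEFAULT_REPEAT_UNIT = "TSPGPGIKEAIGQTKPIE"

SIGNAL_LENGTH = 20
_SIGNAL_POOL = "AILVFMWSTCLG"  # hydrophobic-biased signal-peptide draw


@dataclass(frozen=True)
class GeneratorTruth:
    """Parameters that produced a synthetic artefact, plus the seed."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Expression tables


def gen_expression_table(
    n_reference: int = 200,
    n_nonglue: int = 7,
    sigma_log: float = 0.5,
    focal_spikes: Mapping[str, float] | None = None,
    seed: int = 0,
    baseline_range: tuple[float, float] = (1.0, 1000.0),
) -> tuple[ExpressionTable, GeneratorTruth]:
    """Reference genes under log-normal interspecific noise plus spiked focal genes.

    Per gene, a baseline TPM is drawn log-uniformly over ``baseline_range``;
    each species observes baseline * exp(N(0, sigma_log^2)). Focal genes are
    additionally multiplied by their spike fold in the glue species.
    """
    if n_nonglue < 1:
        raise ValueError("need at least one non-glue species")
    if sigma_log < 0:
        raise ValueError("sigma_log must be non-negative")
    focal_spikes = dict(focal_spikes or {})
    for gene, fold in focal_spikes.items():
        if fold <= 0:
            raise ValueError(f"spike fold for {gene!r} must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"ref_{i + 1:04d}" for i in range(n_reference)] + list(focal_spikes)
    species = ["glue_sp"] + [f"nonglue_{i + 1}" for i in range(n_nonglue)]
    lo, hi = np.log10(baseline_range[0]), np.log10(baseline_range[1])
    baselines = 10 ** rng.uniform(lo, hi, size=len(genes))
    noise = np.exp(rng.normal(0.0, sigma_log, size=(len(genes), len(species))))
    values = baselines[:, None] * noise
    for j, gene in enumerate(focal_spikes):
        values[n_reference + j, 0] *= focal_spikes[gene]
    table = ExpressionTable(
        genes=genes,
        species=species,
        values=values,
        species_role={sp: ("glue" if sp == "glue_sp" else "nonglue") for sp in species},
        gene_class={
            g: ("focal" if g in focal_spikes else "reference") for g in genes
        },
    )
    truth = GeneratorTruth(
        generator="expression_table",
        seed=seed,
        params={
            "n_reference": n_reference,
            "n_nonglue": n_nonglue,
            "sigma_log": sigma_log,
            "focal_spikes": focal_spikes,
            "baseline_range": list(baseline_range),
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# Modular proteins and tracks


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, s: str, rate: float) -> str:
    out = list(s)
    for i, ch in enumerate(out):
        if rng.random() < rate:
            alt = AMINO_ACIDS.replace(ch, "")
            out[i] = alt[rng.integers(len(alt))]
    return "".join(out)


def gen_modular_protein(
    n_domains: int = 2,
    domain_length: int = 390,
    unit: str = DEFAULT_REPEAT_UNIT,
    n_units: int | None = None,
    substitution_rate: float = 0.0,
    seed: int = 0,
    seq_id: str = "synthetic_prit",
) -> tuple[SequenceRecord, ArchitectureAnnotation, GeneratorTruth]:
    """Signal peptide + alternating structured domains and mutated repeat arrays.

    ``n_units`` copies of ``unit`` (drawn uniformly from 12-24 when None) fill
    each of the ``n_domains - 1`` inter-domain arrays; each copy is mutated at
    ``substitution_rate`` per residue. The true segment spans are returned as
    an :class:`ArchitectureAnnotation`.
    """
    if not (1 <= n_domains <= 4):
        raise ValueError("n_domains must be in 1..4")
    if len(unit) < 2:
        raise ValueError("repeat unit must have length >= 2")
    if not (0.0 <= substitution_rate <= 0.3):
        raise ValueError("substitution_rate must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    segments: list[Segment] = []
    pos = 1

    def add(kind: str, label: str, residues: str) -> None:
        nonlocal pos
        parts.append(residues)
        segments.append(Segment(pos, pos + len(residues) - 1, kind, label))
        pos += len(residues)

    signal = "M" + "".join(rng.choice(list(_SIGNAL_POOL), size=SIGNAL_LENGTH - 1))
    add("signal_peptide", "signal", signal)
    units_per_array: list[int] = []
    for d in range(n_domains):
        add("domain", f"domain_{d + 1}", _random_protein(rng, domain_length))
        if d < n_domains - 1:
            k = int(n_units) if n_units is not None else int(rng.integers(12, 25))
            units_per_array.append(k)
            array = "".join(_mutate(rng, unit, substitution_rate) for _ in range(k))
            add("repeat_region", f"repeat_{d + 1}", array)
    seq = SequenceRecord(
        id=seq_id, description="synthetic modular glue protein", residues="".join(parts)
    )
    annotation = ArchitectureAnnotation(
        sequence_id=seq_id, length=len(seq), segments=tuple(segments)
    )
    truth = GeneratorTruth(
        generator="modular_protein",
        seed=seed,
        params={
            "n_domains": n_domains,
            "domain_length": domain_length,
            "unit": unit,
            "units_per_array": units_per_array,
            "substitution_rate": substitution_rate,
        },
    )
    return seq, annotation, truth


def gen_disorder_track(
    annotation: ArchitectureAnnotation,
    mu_repeat: float = 0.85,
    mu_domain: float = 0.2,
    sd: float = 0.1,
    seed: int = 0,
) -> ResidueTrack:
    """Per-residue disorder scores: Gaussian noise around segment-specific
    means (``mu_repeat`` over repeat arrays, ``mu_domain`` elsewhere), clipped
    to [0, 1]."""
    mu = np.full(annotation.length, mu_domain)
    for seg in annotation.of_kind("repeat_region"):
        mu[seg.start - 1 : seg.end] = mu_repeat
    rng = np.random.default_rng(seed)
    values = np.clip(mu + rng.normal(0.0, sd, size=annotation.length), 0.0, 1.0)
    return ResidueTrack(
        sequence_id=annotation.sequence_id, kind="disorder", values=values.tolist()
    )


# ---------------------------------------------------------------------------
# Codon alignments


def _codon_rates(omega: float, kappa: float) -> dict[str, tuple[list[str], np.ndarray]]:
    """Single-nucleotide neighbour rates per sense codon for one omega class."""
    rates: dict[str, tuple[list[str], np.ndarray]] = {}
    for codon in SENSE_CODONS:
        targets: list[str] = []
        r: list[float] = []
        for i in range(3):
            for nt in "ACGT":
                if nt == codon[i]:
                    continue
                alt = codon[:i] + nt + codon[i + 1 :]
                if alt in STOP_CODONS:
                    continue
                rate = kappa if (codon[i], nt) in _TRANSITIONS else 1.0
                if CODON_TABLE[alt] != CODON_TABLE[codon]:
                    rate *= omega
                targets.append(alt)
                r.append(rate)
        rates[codon] = (targets, np.asarray(r))
    return rates


def _neutral_scale(kappa: float) -> float:
    """Scale so that branch lengths are expected substitutions per codon site
    at neutrality (mean total rate over sense codons at omega = 1 equals 1)."""
    neutral = _codon_rates(1.0, kappa)
    mean_total = np.mean([r.sum() for _, r in neutral.values()])
    return 1.0 / mean_total


def _evolve(
    codon: str,
    t: float,
    rates: dict[str, tuple[list[str], np.ndarray]],
    scale: float,
    rng: np.random.Generator,
) -> str:
    while True:
        targets, r = rates[codon]
        total = r.sum() * scale
        t -= rng.exponential(1.0 / total)
        if t <= 0:
            return codon
        codon = targets[int(rng.choice(len(targets), p=r / r.sum()))]


def _balanced_newick(labels: list[str], b: float) -> str:
    if len(labels) == 1:
        return f"{labels[0]}:{b}"
    mid = len(labels) // 2
    left = _balanced_newick(labels[:mid], b)
    right = _balanced_newick(labels[mid:], b)
    return f"({left},{right}):{b}"


def gen_codon_alignment(
    n_taxa: int = 6,
    branch_length: float = 0.2,
    sites_per_class: int = 300,
    omega_classes: Sequence[float] = (0.2, 1.0, 4.0),
    kappa: float = 2.0,
    seed: int = 0,
) -> tuple[CodonAlignmentSet, GeneratorTruth]:
    """Sitewise-independent codon evolution along a balanced tree.

    Each site belongs to one omega class (``sites_per_class`` sites per
    class, in class order); nonsynonymous rates are scaled by the class
    omega, transitions by kappa, and stop codons are unreachable. Branch
    lengths are in expected substitutions per codon site at neutrality.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    if any(w <= 0 for w in omega_classes):
        raise ValueError("omega classes must be positive")
    rng = np.random.default_rng(seed)
    labels = [f"taxon_{i + 1}" for i in range(n_taxa)]
    site_classes: list[float] = []
    for w in omega_classes:
        site_classes.extend([float(w)] * sites_per_class)
    rates_by_class = {float(w): _codon_rates(float(w), kappa) for w in omega_classes}
    scale = _neutral_scale(kappa)

    def split(names: list[str]):
        if len(names) == 1:
            return names[0]
        mid = len(names) // 2
        return (split(names[:mid]), split(names[mid:]))

    topology = split(labels)
    seqs: dict[str, list[str]] = {lb: [] for lb in labels}
    for w in site_classes:
        rates = rates_by_class[w]
        root = SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]

        def descend(node, codon: str) -> None:
            if isinstance(node, str):
                seqs[node].append(codon)
                return
            for child in node:
                descend(child, _evolve(codon, branch_length, rates, scale, rng)
                        if branch_length > 0 else codon)

        descend(topology, root)
    records = [
        SequenceRecord(id=lb, description="", residues="".join(seqs[lb]), alphabet="dna")
        for lb in labels
    ]
    newick = f"({_balanced_newick(labels[: len(labels) // 2], branch_length)},{_balanced_newick(labels[len(labels) // 2 :], branch_length)});"
    alignment = CodonAlignmentSet(records=records, tree=newick)
    truth = GeneratorTruth(
        generator="codon_alignment",
        seed=seed,
        params={
            "n_taxa": n_taxa,
            "branch_length": branch_length,
            "sites_per_class": sites_per_class,
            "omega_classes": [float(w) for w in omega_classes],
            "kappa": kappa,
            "site_classes": site_classes,
        },
    )
    return alignment, truth


# ---------------------------------------------------------------------------
# Pull tests

# published per-treatment (mean kPa, SD kPa, n) summaries
DEFAULT_PULLTEST_SPECS: dict[str, tuple[float, float, int]] = {
    "cure10_40kPa": (33.62, 13.36, 7),
    "cure60_40kPa": (65.51, 37.24, 15),
    "cure60_4kPa": (26.47, 13.65, 7),
    "reference_poison": (0.0, 0.0, 7),
}


def gen_pulltest_records(
    group_specs: Mapping[str, tuple[float, float, int]] | None = None,
    frog_pool: int = 6,
    seed: int = 0,
) -> tuple[list[PullTestRecord], GeneratorTruth]:
    """Trials with Normal(mu, sd) strengths truncated at 0 per treatment.

    Forces are back-computed from strength via F = sigma * A / 1000 with the
    standard brick face area; glue mass is drawn uniformly from the 6-10 mg
    protocol window; frog ids cycle through a pool of ``frog_pool`` animals.
    """
    specs = dict(group_specs or DEFAULT_PULLTEST_SPECS)
    rng = np.random.default_rng(seed)
    area = rectangle_area_mm2(*BRICK_FACE_MM)
    records: list[PullTestRecord] = []
    for treatment, (mu, sd, n) in specs.items():
        if sd < 0 or n < 1:
            raise ValueError(f"{treatment}: need sd >= 0 and n >= 1")
        strengths = np.maximum(0.0, rng.normal(mu, sd, size=n)) if sd > 0 else np.full(n, float(mu))
        for i, s in enumerate(strengths):
            records.append(
                PullTestRecord(
                    frog_id=f"frog_{(i % frog_pool) + 1}",
                    treatment=treatment,
                    glue_mass_mg=float(rng.uniform(6.0, 10.0)),
                    bonded_area_mm2=area,
                    failure_force_n=float(s) * area / 1000.0,
                )
            )
    truth = GeneratorTruth(
        generator="pulltest_records",
        seed=seed,
        params={"group_specs": {k: list(v) for k, v in specs.items()}, "frog_pool": frog_pool},
    )
    return records, truth
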