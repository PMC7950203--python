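"""Seeded generators emulating the pipeline's inputs.

The generators produce, without any download: a replicon-structured bacterial
proteome; per-host replicate PSM tables with planted host-specific proteins
(and near-miss distractors); log-normal iTRAQ ratios with planted shifts; and
an NCR corpus (reference alignment, precursor FASTA, signal-peptide cleavage
table, transcript contigs with embedded coding sequences, and a de-novo
tryptic-fragment list with tag-free decoys). Planted signals carry
construction-guaranteed margins so that the default-threshold pipeline
recovers them exactly; truth tables record every planted label.

All randomness flows from a single integer seed; a fixed seed regenerates
every output byte-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rhizoquant.digestion import DigestOptions, digest
from rhizoquant.io import ProteinRecord, PSMTable
from rhizoquant.ncr_mining import classify_charge, compute_pi

AA20 = "ACDEFGHIKLMNPQRSTVWY"
# residue weights loosely following average proteome composition
AA_WEIGHTS = np.array(
    [8.3, 1.4, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7, 2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
)
HYDROPHOBIC = "AILMFVW"

DEFAULT_REPLICON_PROPORTIONS = {
    "Chromosome": 0.627,
    "pRlvA": 0.170,
    "pRlvB": 0.080,
    "pRlvC": 0.050,
    "pRlvD": 0.033,
    "pRlvE": 0.040,
}


@dataclass(frozen=True)
class NCRSpec:
    """Shape of the generated NCR corpus for one host."""

    n_peptides: int = 52
    cysteine_counts: tuple[int, ...] = (4, 6)
    signal_length_range: tuple[int, int] = (20, 30)
    mature_length_range: tuple[int, int] = (28, 44)
    # target pI class mix; pea-like default (44% cationic)
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"anionic": 0.48, "neutral": 0.08, "cationic": 0.44}
    )
    n_decoy_contigs: int = 40
    n_decoy_peptides: int = 60
    n_reference_sequences: int = 12
    max_class_retries: int = 500


@dataclass(frozen=True)
class GeneratorSpec:
    """Study-shaped generator conditions.

    Defaults mirror the study design: three replicates per host, replicon
    proportions following the published genome shares, over-dispersed
    negative-binomial spectral counts, host-specific plantings at the scale
    of the published calls (28 pea / 25 lentil), and a planted
    accumulated-PSM margin (>= 12) comfortably above the 10-spectra cut-off.
    """

    seed: int = 0
    n_proteins: int = 600
    replicon_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REPLICON_PROPORTIONS)
    )
    n_replicates: int = 3
    psm_mean: float = 20.0
    psm_dispersion: float = 0.3
    n_specific_a: int = 28
    n_specific_b: int = 25
    n_distractors: int = 20
    planted_min_accumulated: int = 12
    detection_fraction: float = 0.7
    itraq_sigma: float = 0.25
    itraq_planted_ratios: tuple[float, ...] = (2.5, 3.2, 0.4)
    ncr: NCRSpec = field(default_factory=NCRSpec)

    def __post_init__(self) -> None:
        total = sum(self.replicon_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("replicon proportions must sum to 1")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be non-negative")
        if self.planted_min_accumulated <= 10:
            warnings.warn(
                "planted accumulated-PSM margin at or below the default call "
                "threshold; recovery is no longer guaranteed"
            )


def _rng(spec: GeneratorSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng((spec.seed, salt))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    p = AA_WEIGHTS / AA_WEIGHTS.sum()
    return "".join(rng.choice(list(AA20), size=length, p=p))


def generate_proteome(spec: GeneratorSpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random proteome with replicon assignments drawn from the proportion map.

    Sequences are 80-600 residues with at least 3 internal tryptic sites
    guaranteed. Returns the records and a truth table of assignments.
    """
    rng = _rng(spec, 1)
    labels = sorted(spec.replicon_proportions)
    probs = np.array([spec.replicon_proportions[l] for l in labels])
    probs = probs / probs.sum()
    records: list[ProteinRecord] = []
    rows = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(80, 601))
        seq = _random_sequence(rng, length)
        internal = [j for j in range(length - 1) if seq[j] in "KR"]
        deficit = 3 - len(internal)
        if deficit > 0:
            positions = rng.choice(length - 1, size=3, replace=False)
            chars = list(seq)
            for pos in positions:
                chars[pos] = "K" if rng.random() < 0.5 else "R"
            seq = "".join(chars)
        replicon = labels[int(rng.choice(len(labels), p=probs))]
        pid = f"SYN_{i + 1:04d}"
        records.append(ProteinRecord(pid, replicon, seq))
        rows.append({"protein_id": pid, "replicon": replicon, "length": len(seq)})
    return records, pd.DataFrame(rows, columns=["protein_id", "replicon", "length"])


def _nb_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """Negative-binomial counts parameterised by mean and dispersion.

    Variance = mean + dispersion * mean^2 (gamma-Poisson mixture).
    """
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape, size=size)
    return rng.poisson(lam)


def generate_psm_tables(
    proteome: Sequence[ProteinRecord], spec: GeneratorSpec
) -> tuple[PSMTable, PSMTable, pd.DataFrame]:
    """Two host PSM tables with planted host-specific proteins.

    Shared proteins receive correlated over-dispersed counts in both hosts
    and are guaranteed detection in at least one replicate per host (so no
    null protein can satisfy the absence criterion). Planted proteins are
    positive in every replicate of their host with accumulated counts at or
    above the planted margin, and exactly zero in the other host. Near-miss
    distractors are present in only ``n_replicates - 1`` replicates or carry
    an accumulated count of 5-9.
    """
    n_special = spec.n_specific_a + spec.n_specific_b + spec.n_distractors
    if n_special > len(proteome):
        raise ValueError("planted + distractor count exceeds proteome size")
    rng = _rng(spec, 2)
    ids = [rec.id for rec in proteome]
    order = rng.permutation(len(ids))
    idx_a = [ids[i] for i in order[: spec.n_specific_a]]
    idx_b = [ids[i] for i in order[spec.n_specific_a : spec.n_specific_a + spec.n_specific_b]]
    idx_d = [
        ids[i]
        for i in order[
            spec.n_specific_a + spec.n_specific_b : n_special
        ]
    ]
    special = set(idx_a) | set(idx_b) | set(idx_d)

    counts_a: dict[str, tuple[int, ...]] = {}
    counts_b: dict[str, tuple[int, ...]] = {}
    rows = []
    nrep = spec.n_replicates

    def planted_counts() -> tuple[int, ...]:
        while True:
            c = _nb_counts(rng, spec.psm_mean, spec.psm_dispersion, nrep) + 1
            if c.sum() >= spec.planted_min_accumulated:
                return tuple(int(x) for x in c)

    for pid in ids:
        if pid in special:
            continue
        if rng.random() > spec.detection_fraction:
            rows.append({"protein_id": pid, "truth": "undetected"})
            continue
        mu = rng.uniform(5.0, 50.0)
        a = _nb_counts(rng, mu, spec.psm_dispersion, nrep)
        b = _nb_counts(rng, mu, spec.psm_dispersion, nrep)
        # guarantee detection in each host so nulls can never pass the
        # absence criterion of the host-specific filter
        if a.sum() == 0:
            a[int(rng.integers(nrep))] = 1
        if b.sum() == 0:
            b[int(rng.integers(nrep))] = 1
        counts_a[pid] = tuple(int(x) for x in a)
        counts_b[pid] = tuple(int(x) for x in b)
        rows.append({"protein_id": pid, "truth": "background"})

    for pid in idx_a:
        counts_a[pid] = planted_counts()
        rows.append({"protein_id": pid, "truth": "planted_A"})
    for pid in idx_b:
        counts_b[pid] = planted_counts()
        rows.append({"protein_id": pid, "truth": "planted_B"})
    for k, pid in enumerate(idx_d):
        host_counts = counts_a if k % 2 == 0 else counts_b
        kind = rng.random()
        if kind < 0.5 and nrep > 1:
            c = list(planted_counts())
            c[int(rng.integers(nrep))] = 0  # present in nrep-1 replicates
            host_counts[pid] = tuple(c)
            rows.append({"protein_id": pid, "truth": "distractor_missing_rep"})
        else:
            total = int(rng.integers(5, 10))
            base = [1] * nrep
            for _ in range(total - nrep):
                base[int(rng.integers(nrep))] += 1
            host_counts[pid] = tuple(base)
            rows.append({"protein_id": pid, "truth": "distractor_low_accumulated"})

    table_a = PSMTable("pea", counts_a, nrep)
    table_b = PSMTable("lentil", counts_b, nrep)
    truth = pd.DataFrame(rows, columns=["protein_id", "truth"])
    return table_a, table_b, truth


def generate_itraq(
    proteome: Sequence[ProteinRecord], spec: GeneratorSpec
) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-protein pea/lentil ratios: log-normal nulls plus planted shifts."""
    rng = _rng(spec, 3)
    ratios: dict[str, float] = {}
    rows = []
    planted = spec.itraq_planted_ratios
    for i, rec in enumerate(proteome):
        if i < len(planted):
            ratio = float(planted[i])
            direction = "pea" if ratio >= 2.0 else ("lentil" if ratio <= 0.5 else "none")
            rows.append({"protein_id": rec.id, "truth": f"planted_{direction}"})
        else:
            ratio = float(np.exp(rng.normal(0.0, spec.itraq_sigma)))
            rows.append({"protein_id": rec.id, "truth": "background"})
        ratios[rec.id] = round(ratio, 4)
    return ratios, pd.DataFrame(rows, columns=["protein_id", "truth"])


# ---------------------------------------------------------------------------
# NCR corpus generation

# conserved defensin-like anchor blocks used in reference and planted matures;
# all are K/R-free so each stays inside a single tryptic fragment
_CORE_BLOCKS = ("CPTDC", "CQSWC", "CDINC")
_CODONS = {
    aa: codons
    for aa, codons in {
        "A": ("GCT", "GCC", "GCA", "GCG"),
        "C": ("TGT", "TGC"),
        "D": ("GAT", "GAC"),
        "E": ("GAA", "GAG"),
        "F": ("TTT", "TTC"),
        "G": ("GGT", "GGC", "GGA", "GGG"),
        "H": ("CAT", "CAC"),
        "I": ("ATT", "ATC", "ATA"),
        "K": ("AAA", "AAG"),
        "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
        "M": ("ATG",),
        "N": ("AAT", "AAC"),
        "P": ("CCT", "CCC", "CCA", "CCG"),
        "Q": ("CAA", "CAG"),
        "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
        "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
        "T": ("ACT", "ACC", "ACA", "ACG"),
        "V": ("GTT", "GTC", "GTA", "GTG"),
        "W": ("TGG",),
        "Y": ("TAT", "TAC"),
    }.items()
}


@dataclass(frozen=True)
class NCRCorpus:
    """All NCR-stage inputs plus the planted truth."""

    reference_alignment: list[tuple[str, str]]
    precursors: list[tuple[str, str]]
    cleavage_table: pd.DataFrame  # columns: ncr_id, cleavage_position
    contigs: list[tuple[str, str]]
    denovo_peptides: list[str]
    truth: pd.DataFrame  # ncr_id, mature, charge_class, contig_id, fragments


def _reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    return "".join(
        _CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in peptide
    )


def _tag_free(rng: np.random.Generator, length: int, forbidden: set[str]) -> str:
    """Random peptide containing none of the forbidden 3-mers (I/L-blind)."""
    while True:
        seq = _random_sequence(rng, length)
        norm = seq.replace("L", "I")
        if not any(
            norm[i : i + 3] in forbidden for i in range(len(norm) - 2)
        ):
            return seq


def _mature_with_class(
    rng: np.random.Generator, spec: NCRSpec, target_class: str, core: str, n_cys_extra: int
) -> str:
    """Mature region containing ``core`` and hitting the target pI class.

    Composition of the variable positions is tuned toward K/R (cationic),
    D/E (anionic) or a balance (neutral) and accepted when the classified pI
    matches; bounded retries, then error.
    """
    pools = {
        "cationic": "KRKRKRGSTANQH",
        "anionic": "DEDEDEGSTANQ",
        "neutral": "GSTANQPVHKDE",
    }
    pool = pools[target_class]
    lo, hi = spec.mature_length_range
    for _ in range(spec.max_class_retries):
        length = int(rng.integers(lo, hi + 1))
        n_var = length - len(core) - n_cys_extra - 2  # 2 for the K anchors
        if n_var < 4:
            continue
        variable = "".join(pool[int(rng.integers(len(pool)))] for _ in range(n_var))
        # split variable region around the anchored, K-delimited core segment
        cut = n_var // 2
        extra_cys = "C" * n_cys_extra
        mature = variable[:cut] + "K" + core + extra_cys + "K" + variable[cut:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            achieved = classify_charge(compute_pi(mature))
        if achieved == target_class:
            return mature
    raise RuntimeError(
        f"could not achieve pI class {target_class!r} within "
        f"{spec.max_class_retries} retries"
    )


def generate_ncr_corpus(spec: GeneratorSpec) -> NCRCorpus:
    """NCR-stage inputs with construction-guaranteed end-to-end recovery.

    Every planted precursor's mature region contains a conserved core block
    (so at least one tryptic fragment passes the tag search), its coding
    sequence is embedded in a contig (half on the reverse strand) among decoy
    contigs, and the emitted de-novo list contains the tag-bearing tryptic
    fragments (up to one missed cleavage) plus tag-free decoy peptides.
    """
    ncr = spec.ncr
    rng = _rng(spec, 4)

    # reference alignment: conserved core columns, variable flanks
    ref_flank_left, ref_flank_right = 4, 4
    core_concat = _CORE_BLOCKS[0] + "GG" + _CORE_BLOCKS[1] + "GG" + _CORE_BLOCKS[2]
    reference: list[tuple[str, str]] = []
    for r in range(ncr.n_reference_sequences):
        left = _random_sequence(rng, ref_flank_left)
        right = _random_sequence(rng, ref_flank_right)
        reference.append((f"REF_{r + 1:02d}", left + core_concat + right))

    forbidden = set()
    for block in _CORE_BLOCKS:
        norm = block.replace("L", "I")
        for i in range(len(norm) - 2):
            forbidden.add(norm[i : i + 3])

    # assign target classes by largest remainder so the realised distribution
    # matches the requested mix as closely as integers allow
    classes = ("anionic", "neutral", "cationic")
    raw = {c: ncr.class_mix.get(c, 0.0) * ncr.n_peptides for c in classes}
    n_assigned = {c: int(raw[c]) for c in classes}
    while sum(n_assigned.values()) < ncr.n_peptides:
        c = max(classes, key=lambda c: raw[c] - n_assigned[c])
        n_assigned[c] += 1
    targets = [c for c in classes for _ in range(n_assigned[c])]

    digest_opts = DigestOptions(max_missed_cleavages=1, min_length=6)
    precursors: list[tuple[str, str]] = []
    cleavage_rows = []
    contigs: list[tuple[str, str]] = []
    denovo: list[str] = []
    truth_rows = []

    for k, target_class in enumerate(targets):
        ncr_id = f"NCR_{k + 1:03d}"
        core = _CORE_BLOCKS[k % len(_CORE_BLOCKS)]
        n_cys_total = ncr.cysteine_counts[k % len(ncr.cysteine_counts)]
        n_cys_extra = max(n_cys_total - core.count("C"), 0)
        mature = _mature_with_class(rng, ncr, target_class, core, n_cys_extra)
        sig_lo, sig_hi = ncr.signal_length_range
        sig_len = int(rng.integers(sig_lo, sig_hi + 1))
        signal = "M" + "".join(
            HYDROPHOBIC[int(rng.integers(len(HYDROPHOBIC)))] for _ in range(sig_len - 1)
        )
        precursor = signal + mature
        precursors.append((ncr_id, precursor))
        cleavage_rows.append({"ncr_id": ncr_id, "cleavage_position": sig_len})

        cds = _reverse_translate(rng, precursor)
        flank5 = "".join("ACGT"[int(rng.integers(4))] for _ in range(int(rng.integers(30, 90))))
        flank3 = "".join("ACGT"[int(rng.integers(4))] for _ in range(int(rng.integers(30, 90))))
        insert = flank5 + cds + "TAA" + flank3
        contig_id = f"CTG_{k + 1:03d}"
        if k % 2 == 1:  # half the embeddings on the reverse strand
            insert = insert.translate(DNA_COMPLEMENT_NT)[::-1]
        contigs.append((contig_id, insert))

        fragments = sorted(
            {
                pep.sequence
                for pep in digest(mature, digest_opts)
                if core.replace("L", "I") in pep.sequence.replace("L", "I")
            }
        )
        denovo.extend(fragments)
        truth_rows.append(
            {
                "ncr_id": ncr_id,
                "mature": mature,
                "charge_class": target_class,
                "contig_id": contig_id,
                "n_fragments": len(fragments),
                "fragments": ";".join(fragments),
            }
        )

    for k in range(ncr.n_decoy_contigs):
        length = int(rng.integers(200, 600))
        contigs.append(
            (
                f"DECOY_CTG_{k + 1:03d}",
                "".join("ACGT"[int(rng.integers(4))] for _ in range(length)),
            )
        )
    for _ in range(ncr.n_decoy_peptides):
        denovo.append(_tag_free(rng, int(rng.integers(8, 20)), forbidden))

    return NCRCorpus(
        reference_alignment=reference,
        precursors=precursors,
        cleavage_table=pd.DataFrame(cleavage_rows, columns=["ncr_id", "cleavage_position"]),
        contigs=contigs,
        denovo_peptides=denovo,
        truth=pd.DataFrame(
            truth_rows,
            columns=["ncr_id", "mature", "charge_class", "contig_id", "n_fragments", "fragments"],
        ),
    )


DNA_COMPLEMENT_NT = str.maketrans("ACGT", "TGCA")


def preset(name: str, seed: int = 0) -> GeneratorSpec:
    """Named generator presets: pea-like, lentil-like, minimal."""
    if name == "pea-like":
        return GeneratorSpec(seed=seed)
    if name == "lentil-like":
        return GeneratorSpec(
            seed=seed,
            n_specific_a=25,
            n_specific_b=28,
            ncr=NCRSpec(
                n_peptides=65,
                class_mix={"anionic": 0.41, "neutral": 0.08, "cationic": 0.51},
            ),
        )
    if name == "minimal":
        return GeneratorSpec(
            seed=seed,
            n_proteins=20,
            n_specific_a=2,
            n_specific_b=2,
            n_distractors=2,
            ncr=NCRSpec(n_peptides=2, n_decoy_contigs=4, n_decoy_peptides=6,
                        class_mix={"anionic": 0.5, "neutral": 0.0, "cationic": 0.5}),
        )
    raise ValueError(f"unknown preset {name!r}")
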