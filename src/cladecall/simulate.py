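"""Seeded synthetic cohorts: Ct tables, truth labels and mutation tables.

The generator emulates the structure of the real experiment: evolved clones
from three ancestral ploidies (1N, 2N, 4N), each measured on the five-gene
panel plus the *ACT1* reference in triplicate reactions for each of two
biological replicates, quantified relative to a diploid ancestor processed
alongside.

Generative model per clone ``c``, gene ``g``, biological replicate ``b``:

1. a true log2 expression ratio ``z ~ Normal(mean_log2[class, g], sd_log2)``
   is drawn once per biological replicate (the ancestor-like class has mean
   zero by the definition of a ratio);
2. the ratio is converted to a cycle threshold through the amplification
   efficiency ``E`` of the gene's primer pair,
   ``Ct = baseline[g] + loading[c, b] - z / log2(1 + E)``, where
   ``loading`` is a per-(clone, bio-replicate) cDNA-input offset in cycles
   that hits every gene equally and therefore cancels under *ACT1*
   normalization;
3. independent ``Normal(0, tech_sd)`` cycle noise is added per technical
   replicate.

Everything is driven by one ``numpy`` generator, so a seed fully determines
the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cladecall.errors import ConfigurationError
from cladecall.signatures import (
    DEFAULT_PANEL,
    REFERENCE_GENE,
    SignatureSet,
    default_signatures,
    driver_of,
)

#: Default ancestor-baseline Ct per gene (cycles), in the ancestor's RNA.
DEFAULT_BASELINE_CT: dict[str, float] = {
    "ACT1": 16.0,
    "HXT2": 24.0,
    "HXT3": 22.0,
    "HXT4": 23.0,
    "HXT6_7": 20.0,
    "SUC2": 25.0,
}

#: Default per-primer-pair amplification efficiency (fraction; 1.0 = doubling).
DEFAULT_EFFICIENCIES: dict[str, float] = {
    "ACT1": 0.97,
    "HXT2": 0.93,
    "HXT3": 0.95,
    "HXT4": 0.91,
    "HXT6_7": 0.96,
    "SUC2": 0.90,
}

#: Default per-ploidy class composition of the evolved cohort
#: (27 haploid-, 32 diploid-, 33 tetraploid-derived clones).
DEFAULT_CLASS_COUNTS: dict[str, dict[str, int]] = {
    "1N": {
        "SNF3_high": 3,
        "SNF3_moderate": 4,
        "MTH1": 10,
        "SNF3_low": 2,
        "IPT1": 3,
        "MOT3": 3,
        "HXT67_amp": 2,
    },
    "2N": {
        "SNF3_high": 7,
        "SNF3_moderate": 6,
        "SNF3_low": 4,
        "RGT2": 2,
        "HXT67_amp": 13,
    },
    "4N": {
        "SNF3_high": 5,
        "SNF3_moderate": 4,
        "SNF3_low": 4,
        "RGT2": 1,
        "HXT67_amp": 19,
    },
}

_PLOIDY_PREFIX = {"1N": "1", "2N": "2", "4N": "3"}

CT_COLUMNS = ("clone", "gene", "bio_rep", "tech_rep", "ct")
TRUTH_COLUMNS = ("clone", "ploidy", "class", "driver")
MUTATION_COLUMNS = ("clone", "gene", "position", "type")


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic qRT-PCR cohort.

    Parameters
    ----------
    class_counts
        ``{ploidy: {class_name: n_clones}}``; counts must be non-negative.
    n_bio, n_tech
        Biological and technical replicates per clone and gene.
    baseline_ct
        Ancestor-baseline Ct per gene (reference gene included).
    efficiencies
        Per-primer amplification efficiency in (0, 1].
    tech_sd
        Technical Ct noise SD in cycles.
    loading_sd
        Per-(clone, bio-replicate) cDNA loading offset SD in cycles; applied
        to all genes of that replicate equally, so it cancels on
        normalization.
    ancestor_id
        Clone id given to the co-processed ancestor (class ``ancestor_like``).
    seed
        Default random seed; ``generate_cohort`` may override it.
    """

    class_counts: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: DEFAULT_CLASS_COUNTS
    )
    n_bio: int = 2
    n_tech: int = 3
    baseline_ct: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_BASELINE_CT
    )
    efficiencies: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_EFFICIENCIES
    )
    tech_sd: float = 0.15
    loading_sd: float = 0.3
    ancestor_id: str = "ancestor"
    seed: int = 0

    def validate(self, signatures: SignatureSet) -> None:
        if self.n_bio < 1 or self.n_tech < 1:
            raise ConfigurationError("n_bio and n_tech must be >= 1")
        if self.tech_sd < 0 or self.loading_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        for ploidy, counts in self.class_counts.items():
            for cls, n in counts.items():
                if n < 0:
                    raise ConfigurationError(
                        f"negative clone count for {cls!r} at ploidy {ploidy!r}"
                    )
                if cls not in signatures:
                    raise ConfigurationError(
                        f"unknown class {cls!r} at ploidy {ploidy!r}: "
                        f"not in the signature set"
                    )
        genes = set(signatures.panel) | {REFERENCE_GENE}
        for g in genes:
            if g not in self.baseline_ct:
                raise ConfigurationError(f"no baseline Ct for gene {g!r}")
            e = self.efficiencies.get(g)
            if e is None:
                raise ConfigurationError(f"no efficiency for gene {g!r}")
            if not (0.0 < e <= 1.0):
                raise ConfigurationError(
                    f"efficiency for {g!r} must be in (0, 1], got {e}"
                )


def _clone_roster(config: CohortConfig) -> pd.DataFrame:
    """Deterministic clone ids: 1xx = 1N-, 2xx = 2N-, 3xx = 4N-derived."""
    rows = []
    for ploidy in sorted(config.class_counts, key=lambda p: _PLOIDY_PREFIX.get(p, p)):
        prefix = _PLOIDY_PREFIX.get(ploidy, "9")
        i = 1
        for cls in config.class_counts[ploidy]:
            for _ in range(int(config.class_counts[ploidy][cls])):
                rows.append((f"{prefix}{i:02d}", ploidy, cls, driver_of(cls)))
                i += 1
    return pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))


def _ct_for_clone(
    rng: np.random.Generator,
    config: CohortConfig,
    signatures: SignatureSet,
    clone: str,
    cls: str,
) -> list[tuple[str, str, int, int, float]]:
    sig = signatures[cls]
    genes = list(signatures.panel) + [REFERENCE_GENE]
    records = []
    for b in range(1, config.n_bio + 1):
        loading = rng.normal(0.0, config.loading_sd) if config.loading_sd else 0.0
        for gene in genes:
            if gene == REFERENCE_GENE:
                z = 0.0
            else:
                gi = signatures.panel.index(gene)
                sd = sig.sd_log2[gi]
                z = sig.mean_log2[gi] + (rng.normal(0.0, sd) if sd else 0.0)
            eff = config.efficiencies[gene]
            ct_mean = config.baseline_ct[gene] + loading - z / np.log2(1.0 + eff)
            for t in range(1, config.n_tech + 1):
                noise = rng.normal(0.0, config.tech_sd) if config.tech_sd else 0.0
                records.append((clone, gene, b, t, float(ct_mean + noise)))
    return records


def generate_cohort(
    config: CohortConfig | None = None,
    signatures: SignatureSet | None = None,
    seed: int | None = None,
    include_ancestor: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full qRT-PCR cohort.

    Returns
    -------
    ct : DataFrame
        Columns ``clone gene bio_rep tech_rep ct``; one row per technical
        reaction, covering panel and reference genes for every clone (and
        the ancestor, unless ``include_ancestor=False``).
    truth : DataFrame
        Columns ``clone ploidy class driver`` (evolved clones only).
    """
    config = config if config is not None else CohortConfig()
    signatures = signatures if signatures is not None else default_signatures()
    config.validate(signatures)
    if seed is not None:
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)

    roster = _clone_roster(config)
    records: list[tuple[str, str, int, int, float]] = []
    if include_ancestor:
        if "ancestor_like" not in signatures:
            raise ConfigurationError(
                "signature set lacks 'ancestor_like'; cannot simulate the ancestor"
            )
        records.extend(
            _ct_for_clone(rng, config, signatures, config.ancestor_id, "ancestor_like")
        )
    for row in roster.itertuples(index=False):
        records.extend(_ct_for_clone(rng, config, signatures, row.clone, row[2]))
    ct = pd.DataFrame(records, columns=list(CT_COLUMNS))
    return ct, roster


@dataclass(frozen=True)
class MutationSimConfig:
    """Design of a synthetic per-clone mutation table.

    ``gene_lengths`` are coding lengths in bp inside a mutational target of
    ``target_length`` bp; mutations land in a gene with probability
    proportional to ``length * weight`` (weight defaults to 1; the remaining
    ``target_length - sum(lengths)`` bp are neutral intergenic/other target).
    ``mean_mutations`` is the Poisson mean of mutations per clone, either a
    single value or per-ploidy.
    """

    gene_lengths: Mapping[str, int]
    target_length: int
    mean_mutations: float | Mapping[str, float] = 4.0
    selection_weights: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.gene_lengths:
            raise ConfigurationError("gene set must not be empty")
        for g, length in self.gene_lengths.items():
            if length <= 0:
                raise ConfigurationError(f"gene {g!r} has non-positive length")
        if sum(self.gene_lengths.values()) > self.target_length:
            raise ConfigurationError("sum of gene lengths exceeds target length")
        means = (
            self.mean_mutations.values()
            if isinstance(self.mean_mutations, Mapping)
            else [self.mean_mutations]
        )
        if any(m < 0 for m in means):
            raise ConfigurationError("mean mutations per clone must be >= 0")


_TYPE_NAMES = ("nonsynonymous", "synonymous", "nonsense", "frameshift")
_TYPE_PROBS = (0.62, 0.22, 0.08, 0.08)


def generate_mutation_table(
    config: MutationSimConfig,
    n_clones: int,
    ploidies: Sequence[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate per-clone gene-level mutation calls.

    Parameters
    ----------
    config
        Generator design (lengths, target, Poisson means, weights).
    n_clones
        Number of clones; ids are ``c001`` ... unless ``ploidies`` is given,
        in which case ids follow the cohort convention.
    ploidies
        Optional per-clone ploidy labels (length ``n_clones``); required when
        ``mean_mutations`` is per-ploidy.

    Returns
    -------
    DataFrame with columns ``clone gene position type``; ``gene`` is
    ``"intergenic"`` for hits outside the gene set, with position within the
    intergenic stretch.
    """
    config.validate()
    if n_clones <= 0:
        raise ConfigurationError("n_clones must be positive")
    if ploidies is not None and len(ploidies) != n_clones:
        raise ConfigurationError("ploidies must have one entry per clone")
    if isinstance(config.mean_mutations, Mapping) and ploidies is None:
        raise ConfigurationError(
            "per-ploidy mean_mutations requires per-clone ploidies"
        )
    rng = np.random.default_rng(config.seed if seed is None else int(seed))

    genes = list(config.gene_lengths)
    lengths = np.array([config.gene_lengths[g] for g in genes], dtype=float)
    weights = np.array(
        [config.selection_weights.get(g, 1.0) for g in genes], dtype=float
    )
    inter_len = float(config.target_length) - lengths.sum()
    mass = np.append(lengths * weights, inter_len)  # last slot: intergenic
    probs = mass / mass.sum()

    rows = []
    seen: set[tuple[str, str, int]] = set()
    for i in range(n_clones):
        if ploidies is not None:
            clone = f"{_PLOIDY_PREFIX.get(ploidies[i], '9')}{i + 1:02d}"
            mean = (
                config.mean_mutations[ploidies[i]]
                if isinstance(config.mean_mutations, Mapping)
                else config.mean_mutations
            )
        else:
            clone = f"c{i + 1:03d}"
            mean = config.mean_mutations
        n_mut = rng.poisson(mean)
        for _ in range(n_mut):
            for _attempt in range(100):
                j = rng.choice(len(mass), p=probs)
                if j < len(genes):
                    gene = genes[j]
                    pos = int(rng.integers(1, config.gene_lengths[gene] + 1))
                    mtype = _TYPE_NAMES[rng.choice(len(_TYPE_NAMES), p=_TYPE_PROBS)]
                else:
                    gene = "intergenic"
                    pos = int(rng.integers(1, max(int(inter_len), 1) + 1))
                    mtype = "intergenic"
                key = (clone, gene, pos)
                if key not in seen:  # (clone, gene, position) must be unique
                    seen.add(key)
                    rows.append((clone, gene, pos, mtype))
                    break
    return pd.DataFrame(rows, columns=list(MUTATION_COLUMNS))
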