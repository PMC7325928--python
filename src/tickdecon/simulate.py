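"""Ground-truthed simulator for low-biomass amplicon contamination.

The generator emulates the statistical structure the decontamination
method assumes:

* a genuine tick community shared across specimens, dominated by one
  endosymbiont-like OTU, sampled per specimen through a
  Dirichlet-multinomial so composition varies realistically;
* genuine template scaling with specimen biomass (females carry more
  microbial template than nymphs or males);
* reagent ("kit") contaminants introduced at homogenization/extraction,
  hitting every homogenized or extracted library — specimens plus
  homogenization and extraction controls — at a roughly constant
  absolute read level per library, so low-biomass libraries end up with
  higher contaminant *fractions*;
* amplification contaminants introduced at PCR, hitting every library
  including the PCR-only amplification controls, which therefore show a
  contaminant profile distinct from the homogenization/extraction one;
* index cross-talk: a small fraction of each OTU's reads misassigned
  uniformly across the other libraries, conserving per-OTU totals.

Everything is deterministic given the seed, and a :class:`GroundTruth`
labels every OTU so classifier calls can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import skbio

from .contaminants import ContaminantCall, RULE_NONE
from .io import CountTable, Dataset, Lineage, SampleCategory, SampleInfo

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "EvalResult",
    "simulate_dataset",
    "apply_crosstalk",
    "evaluate_calls",
]

LABEL_GENUINE = "genuine"
LABEL_KIT = "kit_contaminant"
LABEL_AMP = "amplification_contaminant"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the simulated study.

    Specimen counts default to 100 nymphs / 30 males / 30 females — the
    study design's roughly 5.5:0.3:0.35 hundreds ratio at reduced scale —
    with the control plate kept at full size (12 homogenization, 12
    extraction, 21 amplification controls). ``depth_mean`` is the
    expected number of genuine-template reads for a biomass-1 specimen;
    female biomass defaults to 5x that of nymphs and males.
    ``contaminant_background_reads`` is the expected absolute number of
    contaminant reads entering any single library, independent of
    biomass; ``kit_share`` of it comes from the homogenization/extraction
    reagents and the remainder from PCR reagents.
    """

    n_nymphs: int = 100
    n_males: int = 30
    n_females: int = 30
    n_hc: int = 12
    n_ec: int = 12
    n_ac: int = 21
    n_tick_otus: int = 50
    n_kit_contaminants: int = 10
    n_amp_contaminants: int = 8
    biomass: Mapping[str, float] = field(
        default_factory=lambda: {"nymph": 1.0, "male": 1.0, "female": 5.0}
    )
    depth_mean: float = 2000.0
    depth_dispersion: float = 5.0
    contaminant_background_reads: float = 2000.0
    kit_share: float = 0.85
    crosstalk_rate: float = 0.0002
    dominant_otu_fraction: float = 0.4
    dm_concentration: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_nymphs", "n_males", "n_females", "n_hc", "n_ec", "n_ac",
            "n_tick_otus", "n_kit_contaminants", "n_amp_contaminants",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_tick_otus < 1:
            raise ValueError("need at least one genuine OTU")
        if not (0 < self.dominant_otu_fraction < 1):
            raise ValueError("dominant_otu_fraction must lie in (0, 1)")
        if not (0 <= self.crosstalk_rate < 1):
            raise ValueError("crosstalk_rate must lie in [0, 1)")
        if not (0 <= self.kit_share <= 1):
            raise ValueError("kit_share must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if any(v <= 0 for v in self.biomass.values()):
            raise ValueError("biomass scales must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """True contaminant labels and per-sample contaminant read counts."""

    labels: dict[str, str]
    per_sample_contaminant_reads: pd.Series
    config: GeneratorConfig

    def contaminant_ids(self) -> set[str]:
        return {o for o, lab in self.labels.items() if lab != LABEL_GENUINE}

    def genuine_ids(self) -> set[str]:
        return {o for o, lab in self.labels.items() if lab == LABEL_GENUINE}


@dataclass(frozen=True)
class EvalResult:
    precision: float  # NaN when nothing was flagged
    recall: float  # NaN when there are no true contaminants
    n_flagged: int
    n_true_contaminants: int
    by_rule: dict[str, int]


# ---------------------------------------------------------------------------
# profile and depth draws
# ---------------------------------------------------------------------------

def _geometric_profile(n: int, ratio: float, rng: np.random.Generator) -> np.ndarray:
    """Geometric-decay relative abundances with mild lognormal jitter."""
    w = ratio ** np.arange(n)
    w = w * rng.lognormal(mean=0.0, sigma=0.3, size=n)
    return w / w.sum()


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Gamma-mixed Poisson draw with the given mean and size parameter."""
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _random_tree(otu_ids: Sequence[str], rng: np.random.Generator) -> skbio.TreeNode:
    """Random bifurcating rooted tree over the OTUs with exponential branch
    lengths, built by sequential pair joining."""
    nodes = [skbio.TreeNode(name=o, length=float(rng.exponential(0.1))) for o in otu_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = skbio.TreeNode(length=float(rng.exponential(0.1)), children=[a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _lineage_for(otu_id: str, label: str, rank_seed: int) -> Lineage:
    """Synthetic SILVA-style lineages; names are placeholders, not claims of
    compositional realism."""
    if label == LABEL_KIT:
        genera = ["Pseudomonas", "Acinetobacter", "Enterobacteriaceae-MA", "Gammaproteo-MA"]
        genus = genera[rank_seed % len(genera)]
        return Lineage.from_parts(
            otu_id,
            ["Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales",
             "Pseudomonadaceae", genus, f"{genus}_sp{rank_seed}"],
        )
    if label == LABEL_AMP:
        genera = ["Halomonas", "Shewanella", "Tepidimonas", "Deinococcus"]
        genus = genera[rank_seed % len(genera)]
        return Lineage.from_parts(
            otu_id,
            ["Bacteria", "Proteobacteria", "Gammaproteobacteria", "Oceanospirillales",
             "Halomonadaceae", genus, f"{genus}_sp{rank_seed}"],
        )
    if rank_seed == 0:  # the dominant endosymbiont-like OTU
        return Lineage.from_parts(
            otu_id,
            ["Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales",
             "Midichloriaceae", "Candidatus Midichloria", "endosymbiont"],
        )
    return Lineage.from_parts(
        otu_id,
        ["Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales",
         "TickTaxon", f"TickGenus{rank_seed}", f"TickGenus{rank_seed}_sp"],
    )


# ---------------------------------------------------------------------------
# cross-talk
# ---------------------------------------------------------------------------

def apply_crosstalk(
    table: CountTable, rate: float, seed: int | np.random.Generator
) -> CountTable:
    """Redistribute a Binomial(N_i, rate) share of each OTU's reads.

    Leaked reads are drawn without replacement from the OTU's per-sample
    counts (multivariate hypergeometric, so no sample loses more reads
    than it has) and each leaked read is reassigned uniformly at random
    to one of the other samples. Per-OTU totals and the grand total are
    conserved exactly. With a single sample or rate 0 the table is
    returned unchanged.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = table.counts
    n_otus, n_samples = counts.shape
    if rate == 0 or n_samples < 2 or counts.size == 0:
        return CountTable.from_arrays(counts, table.otu_ids, table.sample_ids)
    for i in range(n_otus):
        row = counts[i]
        total = int(row.sum())
        if total == 0:
            continue
        leaked = int(rng.binomial(total, rate))
        if leaked == 0:
            continue
        sources = rng.multivariate_hypergeometric(row, leaked)
        row -= sources
        for s in np.nonzero(sources)[0]:
            k = int(sources[s])
            others = np.ones(n_samples) / (n_samples - 1)
            others[s] = 0.0
            row += rng.multinomial(k, others)
    return CountTable.from_arrays(counts, table.otu_ids, table.sample_ids)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def simulate_dataset(config: Optional[GeneratorConfig] = None) -> tuple[Dataset, GroundTruth]:
    """Generate one complete dataset plus its ground truth.

    Specimen libraries hold genuine + kit + amplification reads;
    homogenization and extraction controls hold kit + amplification
    reads (they share the kit profile); amplification controls hold
    amplification reads only. Cross-talk is applied last. Deterministic
    given ``config.seed``; per-sample draws proceed in a fixed order
    (nymphs, males, females, then controls), so changing one category's
    biomass leaves the upstream categories' pre-cross-talk draws intact.
    """
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    tick_otus = [f"TICK_{i:03d}" for i in range(config.n_tick_otus)]
    kit_otus = [f"KIT_{i:03d}" for i in range(config.n_kit_contaminants)]
    amp_otus = [f"AMP_{i:03d}" for i in range(config.n_amp_contaminants)]
    otu_ids = tick_otus + kit_otus + amp_otus

    # Shared community profiles (drawn once per dataset).
    d = config.dominant_otu_fraction
    if config.n_tick_otus > 1:
        rest = _geometric_profile(config.n_tick_otus - 1, 0.93, rng) * (1 - d)
        tick_profile = np.concatenate([[d], rest])
    else:
        tick_profile = np.array([1.0])
    kit_profile = (
        _geometric_profile(config.n_kit_contaminants, 0.8, rng)
        if config.n_kit_contaminants
        else np.empty(0)
    )
    amp_profile = (
        _geometric_profile(config.n_amp_contaminants, 0.8, rng)
        if config.n_amp_contaminants
        else np.empty(0)
    )

    samples: list[tuple[str, SampleCategory]] = []
    for i in range(config.n_nymphs):
        samples.append((f"N{i:03d}", SampleCategory.NYMPH))
    for i in range(config.n_males):
        samples.append((f"M{i:03d}", SampleCategory.MALE))
    for i in range(config.n_females):
        samples.append((f"F{i:03d}", SampleCategory.FEMALE))
    for i in range(config.n_hc):
        samples.append((f"HC{i:02d}", SampleCategory.HOMOGENIZATION_CONTROL))
    for i in range(config.n_ec):
        samples.append((f"EC{i:02d}", SampleCategory.EXTRACTION_CONTROL))
    for i in range(config.n_ac):
        samples.append((f"AC{i:02d}", SampleCategory.AMPLIFICATION_CONTROL))
    if not samples:
        raise ValueError("configuration yields zero samples")

    kit_mean = config.contaminant_background_reads * config.kit_share
    amp_mean = config.contaminant_background_reads * (1 - config.kit_share)

    counts = np.zeros((len(otu_ids), len(samples)), dtype=np.int64)
    n_tick = config.n_tick_otus
    n_kit = config.n_kit_contaminants
    for j, (sid, cat) in enumerate(samples):
        col = np.zeros(len(otu_ids), dtype=np.int64)
        if cat.is_specimen:
            scale = config.biomass.get(cat.value, 1.0)
            genuine_total = _negbin(rng, config.depth_mean * scale, config.depth_dispersion)
            if genuine_total > 0:
                p = rng.dirichlet(tick_profile * config.dm_concentration)
                col[:n_tick] = rng.multinomial(genuine_total, p)
        if n_kit and cat != SampleCategory.AMPLIFICATION_CONTROL:
            kit_total = int(rng.poisson(kit_mean))
            if kit_total:
                col[n_tick : n_tick + n_kit] = rng.multinomial(kit_total, kit_profile)
        if config.n_amp_contaminants:
            amp_total = int(rng.poisson(amp_mean))
            if amp_total:
                col[n_tick + n_kit :] = rng.multinomial(amp_total, amp_profile)
        counts[:, j] = col

    table = CountTable.from_arrays(counts, otu_ids, [s for s, _ in samples])
    if table.grand_total() == 0:
        raise ValueError("configuration yields an empty dataset (zero depth)")
    table = apply_crosstalk(table, config.crosstalk_rate, rng)

    labels = (
        {o: LABEL_GENUINE for o in tick_otus}
        | {o: LABEL_KIT for o in kit_otus}
        | {o: LABEL_AMP for o in amp_otus}
    )
    taxonomy = {}
    for k, o in enumerate(tick_otus):
        taxonomy[o] = _lineage_for(o, LABEL_GENUINE, k)
    for k, o in enumerate(kit_otus):
        taxonomy[o] = _lineage_for(o, LABEL_KIT, k)
    for k, o in enumerate(amp_otus):
        taxonomy[o] = _lineage_for(o, LABEL_AMP, k)
    metadata = {sid: SampleInfo(sample_id=sid, category=cat) for sid, cat in samples}
    tree = _random_tree(otu_ids, rng)

    contaminant_rows = [o for o in otu_ids if labels[o] != LABEL_GENUINE]
    per_sample = table.data.loc[contaminant_rows].sum(axis=0)

    dataset = Dataset(table=table, metadata=metadata, taxonomy=taxonomy, tree=tree)
    truth = GroundTruth(labels=labels, per_sample_contaminant_reads=per_sample, config=config)
    return dataset, truth


def evaluate_calls(
    calls: Sequence[ContaminantCall], truth: GroundTruth
) -> EvalResult:
    """Score classifier calls against the generator's ground truth."""
    call_ids = {c.otu_id for c in calls}
    if call_ids != set(truth.labels):
        raise ValueError("calls and ground truth cover different OTU sets")
    flagged = {c.otu_id for c in calls if c.is_contaminant}
    true_set = truth.contaminant_ids()
    tp = len(flagged & true_set)
    precision = tp / len(flagged) if flagged else float("nan")
    recall = tp / len(true_set) if true_set else float("nan")
    by_rule: dict[str, int] = {}
    for c in calls:
        if c.rule != RULE_NONE:
            by_rule[c.rule] = by_rule.get(c.rule, 0) + 1
    return EvalResult(
        precision=precision,
        recall=recall,
        n_flagged=len(flagged),
        n_true_contaminants=len(true_set),
        by_rule=by_rule,
    )
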