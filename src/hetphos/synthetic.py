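"""Synthetic datasets with the statistical structure the method assumes.

The generator emulates the ingredients the predictor exploits: a background
proteome of i.i.d. sequences, substrate proteins carrying a position-specific
motif around their true S/T phosphosites, and annotation namespaces in which
planted terms are over- or under-represented among substrates at a chosen
odds ratio. Term independence, uniform residue composition and fixed protein
length are deliberate simplifications (the statistics under test do not
depend on them).

Everything is a pure function of (config, seed): the master seed spawns one
child stream per component (proteome, sites, annotations, structure), and a
grandchild per namespace, so adding a namespace never perturbs the sequences
or sites.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .datatypes import (
    AA_ORDER,
    Dataset,
    FeatureMatrix,
    PhosphoSite,
    Protein,
    StructureTable,
)

_AA = np.array(list(AA_ORDER))


def _default_motif() -> Dict[int, Dict[str, float]]:
    # Minimal proline-directed consensus (S/T-P): one informative flanking
    # position, emulating families whose sequence signal alone is weak and
    # where functional features carry much of the discrimination.
    return {1: {"P": 1.0}}


@dataclass(frozen=True)
class NamespaceConfig:
    """Planted-term layout for one annotation namespace."""

    name: str
    n_terms: int = 40
    background_term_prob: float = 0.1
    n_enriched_terms: int = 4
    enriched_odds_ratio: float = 8.0
    n_depleted_terms: int = 2
    depleted_odds_ratio: float = 0.125

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError(f"{self.name}: n_terms must be >= 1")
        if not 0.0 <= self.background_term_prob <= 1.0:
            raise ValueError(f"{self.name}: background_term_prob outside [0,1]")
        if self.enriched_odds_ratio <= 0 or self.depleted_odds_ratio <= 0:
            raise ValueError(f"{self.name}: odds ratios must be > 0")
        if self.n_enriched_terms < 0 or self.n_depleted_terms < 0:
            raise ValueError(f"{self.name}: negative term counts")
        if self.n_enriched_terms + self.n_depleted_terms > self.n_terms:
            raise ValueError(
                f"{self.name}: more planted terms than n_terms "
                f"({self.n_enriched_terms}+{self.n_depleted_terms} > {self.n_terms})"
            )


def _default_namespaces() -> List[NamespaceConfig]:
    return [
        NamespaceConfig(name)
        for name in ("kegg", "go_bp", "go_cc", "go_mf", "pfam", "interpro", "string_ppi")
    ]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults give 500 background + 50 substrate proteins with two true sites
    each (100 positive sites, comparable to a typical kinase family's sample
    size) and seven annotation namespaces with a handful of planted terms.
    """

    n_background: int = 500
    n_substrates: int = 50
    protein_length: int = 60
    family: str = "CDK"
    motif: Mapping[int, Mapping[str, float]] = field(default_factory=_default_motif)
    motif_strength: float = 0.8
    namespaces: Sequence[NamespaceConfig] = field(default_factory=_default_namespaces)
    sites_per_substrate: int = 2
    seed: int = 0
    half_window: int = 4

    def __post_init__(self) -> None:
        if self.n_background < 1 or self.n_substrates < 1:
            raise ValueError("protein counts must be positive")
        if self.sites_per_substrate < 1:
            raise ValueError("sites_per_substrate must be >= 1")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must be in [0,1]")
        for off, dist in self.motif.items():
            if off == 0 or not -self.half_window <= off <= self.half_window:
                raise ValueError(f"motif offset {off} outside -h..h (0 excluded)")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"motif distribution at offset {off} does not sum to 1")
        need = (2 * self.half_window + 1) * self.sites_per_substrate + 2 * self.half_window
        if self.protein_length < need:
            raise ValueError(
                f"protein_length {self.protein_length} too short for "
                f"{self.sites_per_substrate} non-overlapping interior sites"
            )


def planted_enriched_terms(config: SynthConfig) -> Dict[str, List[str]]:
    """Term ids planted as over-represented, per namespace."""
    return {
        ns.name: [f"{ns.name}:enr{i + 1:02d}" for i in range(ns.n_enriched_terms)]
        for ns in config.namespaces
    }


def planted_depleted_terms(config: SynthConfig) -> Dict[str, List[str]]:
    """Term ids planted as under-represented, per namespace."""
    return {
        ns.name: [f"{ns.name}:dep{i + 1:02d}" for i in range(ns.n_depleted_terms)]
        for ns in config.namespaces
    }


def _tilt(p: float, odds_ratio: float) -> float:
    """Tilt a Bernoulli probability by an odds ratio: p' = OR*p / (1-p+OR*p)."""
    return odds_ratio * p / (1.0 - p + odds_ratio * p)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 20, size=length)


def _pick_site_positions(
    rng: np.random.Generator, length: int, k: int, h: int
) -> List[int]:
    """k 1-based positions, >= h+1 from each terminus, windows non-overlapping."""
    lo, hi = h + 1, length - h  # inclusive, 1-based
    candidates = rng.permutation(np.arange(lo, hi + 1))
    chosen: List[int] = []
    for pos in candidates:
        if all(abs(int(pos) - q) >= 2 * h + 1 for q in chosen):
            chosen.append(int(pos))
            if len(chosen) == k:
                return sorted(chosen)
    raise ValueError(f"could not place {k} non-overlapping sites in length {length}")


def generate_dataset(config: SynthConfig) -> Dataset:
    """Generate a Dataset fully determined by ``config`` (including its seed)."""
    root = np.random.SeedSequence(config.seed)
    ss_prot, ss_site, ss_ann, ss_struct = root.spawn(4)
    rng_prot = np.random.default_rng(ss_prot)
    rng_site = np.random.default_rng(ss_site)
    rng_struct = np.random.default_rng(ss_struct)
    h = config.half_window
    L = config.protein_length

    st_codes = {AA_ORDER.index("S"), AA_ORDER.index("T")}

    proteome: Dict[str, Protein] = {}
    for i in range(config.n_background):
        seq = _random_sequence(rng_prot, L)
        while not st_codes & set(seq.tolist()):  # guarantee >= 1 S/T
            seq = _random_sequence(rng_prot, L)
        proteome[f"bg{i + 1:04d}"] = Protein(f"bg{i + 1:04d}", "".join(_AA[seq]))

    substrate_base = [
        _random_sequence(rng_prot, L) for _ in range(config.n_substrates)
    ]

    # Plant motif windows at the true sites (sites stream only).
    sites: List[PhosphoSite] = []
    motif = {off: (list(d.keys()), list(d.values())) for off, d in config.motif.items()}
    for i, seq in enumerate(substrate_base):
        pid = f"sub{i + 1:04d}"
        positions = _pick_site_positions(rng_site, L, config.sites_per_substrate, h)
        for pos in positions:
            center = "S" if rng_site.random() < 0.5 else "T"
            seq[pos - 1] = AA_ORDER.index(center)
            for off in range(-h, h + 1):
                if off == 0:
                    continue
                if off in motif and rng_site.random() < config.motif_strength:
                    residues, probs = motif[off]
                    aa = residues[rng_site.choice(len(residues), p=probs)]
                else:
                    aa = AA_ORDER[rng_site.integers(0, 20)]
                seq[pos - 1 + off] = AA_ORDER.index(aa)
            sites.append(PhosphoSite(pid, pos, center, config.family))
        proteome[pid] = Protein(pid, "".join(_AA[seq]))

    protein_ids = list(proteome)
    is_substrate = np.array([pid.startswith("sub") for pid in protein_ids])

    # Annotations: one grandchild stream per namespace, ordered as configured.
    matrices: Dict[str, FeatureMatrix] = {}
    ns_seeds = ss_ann.spawn(len(config.namespaces))
    for ns, ns_seed in zip(config.namespaces, ns_seeds):
        rng_ns = np.random.default_rng(ns_seed)
        terms = (
            [f"{ns.name}:enr{i + 1:02d}" for i in range(ns.n_enriched_terms)]
            + [f"{ns.name}:dep{i + 1:02d}" for i in range(ns.n_depleted_terms)]
            + [
                f"{ns.name}:bg{i + 1:03d}"
                for i in range(ns.n_terms - ns.n_enriched_terms - ns.n_depleted_terms)
            ]
        )
        p0 = ns.background_term_prob
        probs = np.full((len(protein_ids), ns.n_terms), p0)
        probs[is_substrate, : ns.n_enriched_terms] = _tilt(p0, ns.enriched_odds_ratio)
        probs[
            is_substrate,
            ns.n_enriched_terms : ns.n_enriched_terms + ns.n_depleted_terms,
        ] = _tilt(p0, ns.depleted_odds_ratio)
        inc = (rng_ns.random(probs.shape) < probs).astype(np.uint8)
        matrices[ns.name] = FeatureMatrix(ns.name, list(protein_ids), terms, inc)

    # Structure: uniform over {H,E,C} x {0..6} for every residue.
    structure = StructureTable()
    ss_alpha = np.array(list("HEC"))
    for pid in protein_ids:
        labels = "".join(ss_alpha[rng_struct.integers(0, 3, size=L)])
        accs = rng_struct.integers(0, 7, size=L)
        structure.add_protein(pid, labels, accs.tolist())

    ds = Dataset(proteome=proteome, sites=sites, matrices=matrices, structure=structure)
    ds.validate()
    return ds


def withhold_substrates(dataset: Dataset, protein_ids) -> Tuple[Dataset, List[PhosphoSite]]:
    """Hide the listed substrates' sites, returning (dataset, hidden sites).

    The hidden proteins keep their sequences and annotations but lose their
    site records, so to the pipeline they look like background proteins. This
    is the evaluation design for the proteome scan: a correct scan should
    rank the hidden substrates among the candidates and recover their sites.
    """
    hidden_ids = set(protein_ids)
    unknown = hidden_ids - set(dataset.proteome)
    if unknown:
        raise ValueError(f"unknown proteins to withhold: {sorted(unknown)[:5]}")
    hidden = [s for s in dataset.sites if s.protein_id in hidden_ids]
    visible = [s for s in dataset.sites if s.protein_id not in hidden_ids]
    reduced = Dataset(
        proteome=dataset.proteome,
        sites=visible,
        matrices=dataset.matrices,
        structure=dataset.structure,
    )
    return reduced, hidden


def null_dataset(config: SynthConfig) -> Dataset:
    """Same generator with all odds ratios forced to 1 and motif strength 0."""
    null_ns = [
        dataclasses.replace(ns, enriched_odds_ratio=1.0, depleted_odds_ratio=1.0)
        for ns in config.namespaces
    ]
    null_cfg = dataclasses.replace(config, motif_strength=0.0, namespaces=null_ns)
    return generate_dataset(null_cfg)
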