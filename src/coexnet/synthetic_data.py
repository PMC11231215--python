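"""Multi-phenotype synthetic expression data with planted structure.

The generator emulates the statistical structure the downstream analysis
assumes: several phenotype-labeled expression matrices over a shared gene
universe, with planted co-expression modules that partially overlap
across phenotypes (exact, controlled gene-set Jaccard), phenotype-private
modules, group mean shifts against a designated reference phenotype, and
an annotation database whose signal terms exactly cover the planted
modules.

Co-expression inside a module follows a one-factor Gaussian model
x_g = a z + eps with z standard normal per sample and eps ~ N(0, sd^2),
so the within-module pairwise correlation is a^2 / (a^2 + sd^2) and the
population MI between two module genes has the Gaussian closed form
-0.5 ln(1 - rho^2) — both available as exact oracles.  Values are
emitted directly on the log2 scale; no count model is attempted.

Cross-phenotype overlap is realized by explicit index sets (a shared core
plus per-phenotype private genes), so target Jaccards are exact by
construction rather than approximated by resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .enrichment import AnnotationDB
from .mi_network import ExpressionMatrix


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


@dataclass
class PlantedModule:
    """One planted co-expression module, possibly shared across phenotypes.

    genes_by_phenotype maps phenotype -> set of gene indices (empty/absent
    in phenotypes where the module does not exist); target_jaccard records
    the designed pairwise cross-phenotype gene-set Jaccard values.
    """

    module_id: str
    genes_by_phenotype: dict  # phenotype -> frozenset of int gene indices
    loading: float = 1.0
    target_jaccard: dict = field(default_factory=dict)  # (phen_a, phen_b) -> float
    description: str = "planted co-expression module"

    def __post_init__(self):
        if self.loading <= 0:
            raise ValueError("loading must be positive")
        self.genes_by_phenotype = {
            p: frozenset(g) for p, g in self.genes_by_phenotype.items() if g
        }
        for (pa, pb), target in self.target_jaccard.items():
            a = self.genes_by_phenotype.get(pa, frozenset())
            b = self.genes_by_phenotype.get(pb, frozenset())
            realized = len(a & b) / len(a | b) if (a | b) else 0.0
            if abs(realized - target) > 1e-9:
                raise ValueError(
                    f"module {self.module_id}: realized Jaccard {realized:.4f} "
                    f"for ({pa}, {pb}) does not match target {target:.4f}"
                )

    @property
    def phenotypes(self) -> list:
        return sorted(self.genes_by_phenotype)

    @property
    def all_genes(self) -> frozenset:
        return frozenset().union(*self.genes_by_phenotype.values())

    @property
    def is_shared(self) -> bool:
        return len(self.genes_by_phenotype) >= 2


def shared_module(
    module_id: str,
    phenotypes,
    size: int,
    core_size: int,
    start_index: int,
    loading: float = 1.0,
    description: str = "planted co-expression module",
) -> PlantedModule:
    """Build a module of ``size`` genes per phenotype sharing a common
    core of ``core_size`` genes; every cross-phenotype pair then has
    exact Jaccard core / (2*size - core)."""
    if not 0 < core_size <= size:
        raise ValueError("need 0 < core_size <= size")
    phenotypes = list(phenotypes)
    core = frozenset(range(start_index, start_index + core_size))
    nxt = start_index + core_size
    sets = {}
    for p in phenotypes:
        private = frozenset(range(nxt, nxt + size - core_size))
        nxt += size - core_size
        sets[p] = core | private
    jac = core_size / (2 * size - core_size) if len(phenotypes) > 1 else None
    targets = {
        (a, b): jac for a, b in combinations(sorted(phenotypes), 2)
    } if len(phenotypes) > 1 else {}
    return PlantedModule(module_id, sets, loading, targets, description)


@dataclass
class SyntheticDesign:
    """Full specification of one synthetic multi-phenotype dataset."""

    phenotype_names: list
    reference: str
    n_genes: int
    n_samples_per_phenotype: dict  # phenotype -> count
    planted_modules: list
    noise_sd: float
    de_effects: dict = field(default_factory=dict)  # gene idx -> {phenotype: log2 shift}
    annotation_terms: list = field(default_factory=list)  # (term id, gene idx set, desc)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.reference not in self.phenotype_names:
            raise ValueError("reference must be one of the phenotypes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for p in self.phenotype_names:
            if self.n_samples_per_phenotype.get(p, 0) < 3:
                raise ValueError(f"phenotype {p}: need at least 3 samples")
        for mod in self.planted_modules:
            for p, genes in mod.genes_by_phenotype.items():
                if p not in self.phenotype_names:
                    raise ValueError(
                        f"module {mod.module_id} names unknown phenotype {p}"
                    )
                if genes and max(genes) >= self.n_genes:
                    raise ValueError(
                        f"module {mod.module_id} gene index out of range"
                    )
        for p in self.phenotype_names:
            seen: set = set()
            for mod in self.planted_modules:
                genes = mod.genes_by_phenotype.get(p, frozenset())
                if seen & genes:
                    raise ValueError(
                        f"overlapping module gene sets in phenotype {p}"
                    )
                seen |= genes

    @property
    def gene_ids(self) -> list:
        return [_gene_id(i) for i in range(self.n_genes)]


def benchmark_design(seed: int = 0) -> SyntheticDesign:
    """The default benchmark: 5 phenotypes (reference 'Normal' plus four
    tumor subtypes), 2,000 genes, 100 samples each, 8 planted modules of
    20-40 genes with loading 1 and residual sd 0.7 (within-module
    correlation 1/1.49 ~ 0.67).

    Six modules span two or more phenotypes (the cross-phenotype module
    families that should surface as similarity clusters) with exact
    pairwise Jaccards between 1.0 and ~0.32; two are phenotype-private.
    Shared modules carry immune/inflammation descriptions so keyword
    selection picks their communities up; private ones do not.
    """
    phens = ["Normal", "LumA", "LumB", "Her2", "Basal"]
    cancer = phens[1:]
    mods = [
        shared_module("M1", phens, 30, 30, 0, description="innate immune response (planted)"),
        shared_module("M2", phens, 30, 24, 30, description="interferon mediated antiviral immune response (planted)"),
        shared_module("M3", cancer, 24, 16, 84, description="antigen processing and presentation, adaptive immune process (planted)"),
        shared_module("M4", phens, 27, 24, 132, description="T cell mediated immunity (planted)"),
        shared_module("M5", ["Normal", "LumA"], 20, 15, 171, description="inflammatory response to wounding (planted)"),
        shared_module("M6", ["LumA"], 25, 25, 196, description="lipid metabolic process (planted)"),
        shared_module("M7", ["Basal"], 40, 40, 221, description="mitotic cell cycle (planted)"),
        shared_module("M8", phens, 25, 12, 261, description="adaptive immune response signaling (planted)"),
    ]
    de: dict = {}
    for g in mods[0].all_genes:  # M1 over-expressed in every tumor subtype
        de[g] = {p: 1.5 for p in cancer}
    for g in mods[6].all_genes:  # Basal-private module over-expressed there
        de[g] = {"Basal": 1.5}
    for g in range(1900, 1930):  # background under-expressed genes in LumB
        de[g] = {"LumB": -1.5}
    return SyntheticDesign(
        phenotype_names=phens,
        reference="Normal",
        n_genes=2000,
        n_samples_per_phenotype={p: 100 for p in phens},
        planted_modules=mods,
        noise_sd=0.7,
        de_effects=de,
        seed=seed,
    )


def small_design(seed: int = 0) -> SyntheticDesign:
    """A reduced design for quick end-to-end runs: 3 phenotypes, 600
    genes, 60 samples, 4 planted modules (3 shared, 1 private)."""
    phens = ["Normal", "TumorA", "TumorB"]
    mods = [
        shared_module("M1", phens, 20, 20, 0, description="innate immune response (planted)"),
        shared_module("M2", phens, 20, 14, 20, description="inflammatory signaling (planted)"),
        shared_module("M3", ["TumorA", "TumorB"], 16, 10, 62, description="adaptive immune response (planted)"),
        shared_module("M4", ["TumorB"], 18, 18, 90, description="oxidative metabolism (planted)"),
    ]
    de = {g: {"TumorA": 1.5, "TumorB": 1.5} for g in mods[0].all_genes}
    de.update({g: {"TumorB": -1.5} for g in range(560, 580)})
    return SyntheticDesign(
        phenotype_names=phens,
        reference="Normal",
        n_genes=600,
        n_samples_per_phenotype={p: 60 for p in phens},
        planted_modules=mods,
        noise_sd=0.7,
        de_effects=de,
        seed=seed,
    )


def generate_expression(design: SyntheticDesign) -> dict:
    """Simulate one expression matrix per phenotype.

    Module genes follow x_g = a z + eps with a module-shared latent factor
    z per sample; all other genes are independent N(0, noise_sd^2) noise;
    mean shifts from de_effects are added to the named phenotype's
    samples.  Bit-identical for identical design + seed.
    """
    rng = np.random.default_rng(design.seed)
    genes = design.gene_ids
    out = {}
    for phen in design.phenotype_names:
        n = design.n_samples_per_phenotype[phen]
        values = rng.normal(0.0, design.noise_sd, size=(design.n_genes, n))
        for mod in design.planted_modules:
            idx = sorted(mod.genes_by_phenotype.get(phen, frozenset()))
            if not idx:
                continue
            z = rng.standard_normal(n)
            values[idx, :] += mod.loading * z[None, :]
        for g, shifts in design.de_effects.items():
            if phen in shifts:
                values[g, :] += shifts[phen]
        out[phen] = ExpressionMatrix(
            genes=genes,
            samples=[f"{phen}_{i:03d}" for i in range(n)],
            values=values,
            phenotype=phen,
        )
    return out


def generate_annotations(
    design: SyntheticDesign,
    n_decoy_terms: int = 50,
    decoy_size: int = 20,
) -> AnnotationDB:
    """Annotation database over the design's gene universe.

    One *signal* term per planted module, exactly covering the union of
    that module's per-phenotype gene sets, plus ``n_decoy_terms`` decoy
    terms of genes drawn uniformly from the universe (expected overlap
    with any K-gene module is hypergeometric, K * decoy_size / n_genes),
    plus any extra terms listed on the design.  Decoys are reproducible
    from the design seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 977]))
    terms = {}
    for mod in design.planted_modules:
        terms[f"TERM:{mod.module_id}"] = (
            mod.description,
            frozenset(_gene_id(i) for i in mod.all_genes),
        )
    for i in range(n_decoy_terms):
        draw = rng.choice(design.n_genes, size=decoy_size, replace=False)
        terms[f"DECOY:{i:03d}"] = (
            "random decoy gene set",
            frozenset(_gene_id(int(g)) for g in draw),
        )
    for tid, gene_idx, desc in design.annotation_terms:
        terms[tid] = (desc, frozenset(_gene_id(i) for i in gene_idx))
    return AnnotationDB(terms, frozenset(design.gene_ids))


def planted_truth(design: SyntheticDesign) -> dict:
    """Deterministic ground-truth tables for recovery tests.

    Returns 'membership' (phenotype, module, gene), 'module_jaccard'
    (module, phenotype pair, realized gene-set Jaccard), and 'de_labels'
    (gene, phenotype, over/under/ns at the |shift| >= 1 convention) as
    DataFrames.
    """
    mem = [
        (p, mod.module_id, _gene_id(i))
        for mod in design.planted_modules
        for p in mod.phenotypes
        for i in sorted(mod.genes_by_phenotype[p])
    ]
    jac = []
    for mod in design.planted_modules:
        for pa, pb in combinations(mod.phenotypes, 2):
            a = mod.genes_by_phenotype[pa]
            b = mod.genes_by_phenotype[pb]
            jac.append((mod.module_id, pa, pb, len(a & b) / len(a | b)))
    de = []
    for g, shifts in sorted(design.de_effects.items()):
        for p in design.phenotype_names:
            if p == design.reference:
                continue
            shift = shifts.get(p, 0.0)
            label = "over" if shift >= 1 else "under" if shift <= -1 else "ns"
            de.append((_gene_id(g), p, shift, label))
    return {
        "membership": pd.DataFrame(
            mem, columns=["phenotype", "module", "gene"]
        ),
        "module_jaccard": pd.DataFrame(
            jac, columns=["module", "phenotype_a", "phenotype_b", "jaccard"]
        ),
        "de_labels": pd.DataFrame(
            de, columns=["gene", "phenotype", "shift", "label"]
        ),
    }


def module_families(design: SyntheticDesign) -> list:
    """Planted modules present in two or more phenotypes — the families
    expected to surface as cross-network similarity clusters."""
    return [m for m in design.planted_modules if m.is_shared]


def within_module_correlation(loading: float, noise_sd: float) -> float:
    """Population pairwise correlation a^2 / (a^2 + sd^2) of the
    one-factor model."""
    return loading**2 / (loading**2 + noise_sd**2)


def gaussian_mi(rho: float) -> float:
    """Population MI of a bivariate Gaussian, -0.5 ln(1 - rho^2), nats."""
    return -0.5 * np.log(1 - rho**2)
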