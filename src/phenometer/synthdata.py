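"""Synthetic pathway-structured mutant phenotype libraries with ground truth.

The generator emulates the study design used throughout this package's
validation: a panel of metabolism mutants spanning the steps of a metabolic
pathway, with *allelic pairs* — independent mutations in the same gene — that
are expected to share a metabolic phenotype up to noise.  Each pathway has a
sparse base log-signature over the metabolome; genes within a pathway deviate
from it by gene-specific offsets; each allele applies a random severity to
its gene's signature and adds log-normal replicate noise:

    SIR_m = exp(severity * signature_m + eps_m),   eps_m ~ N(0, sigma)

so all fold-changes are strictly positive and many responses fall below the
1.5-fold filter, as in real data.  Ground truth (phenotype -> gene ->
pathway) is returned alongside, making allelic-twin recovery and
within/between-pathway contrasts directly testable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .phenotypes import MetaboliteKey, Phenotype, write_phenotype

__all__ = [
    "PathwaySpec",
    "SimScenario",
    "default_scenario",
    "coupled_scenario",
    "generate_library",
    "inject_platform_bias",
    "write_library",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwaySpec:
    """One pathway: its member genes and (optionally) a fixed base
    log-signature over all metabolites; if None the signature is drawn from
    N(0, base_sd) on a random responding subset."""

    name: str
    genes: tuple[str, ...]
    base_signature: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has no genes")


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for a synthetic mutant library.

    n_metabolites: metabolome size.
    pathways: pathway specs (genes + optional fixed base signatures).
    responding_fraction: fraction of metabolites responding per pathway.
    base_sd: SD of base log-signature entries (natural-log units) on the
        responding subset; ~e-fold typical responses with multi-ten-fold
        tails, matching strong metabolism mutants.
    gene_offset_sd: within-pathway divergence of gene signatures.
    severity_range: per-allele multiplicative severity on the signature.
    noise_sd: log-scale replicate noise sigma.
    alleles_per_gene: independent mutants generated per gene.
    coupled_genes: optional pair of genes forced to share identical
        signatures — the biochemically-coupled hard discrimination case.
    """

    n_metabolites: int = 100
    pathways: tuple[PathwaySpec, ...] = ()
    responding_fraction: float = 0.3
    base_sd: float = 1.0
    gene_offset_sd: float = 0.5
    severity_range: tuple[float, float] = (0.7, 1.3)
    noise_sd: float = 0.1
    alleles_per_gene: int = 2
    seed: int = 0
    coupled_genes: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        if not self.pathways:
            raise ValueError("scenario needs at least one pathway")
        if not 0.0 < self.responding_fraction <= 1.0:
            raise ValueError("responding_fraction must be in (0, 1]")
        lo, hi = self.severity_range
        if not (0.0 < lo <= hi):
            raise ValueError("severity_range must satisfy 0 < lo <= hi")
        if self.noise_sd < 0 or self.gene_offset_sd < 0:
            raise ValueError("noise_sd and gene_offset_sd must be >= 0")
        if self.alleles_per_gene < 1:
            raise ValueError("alleles_per_gene must be >= 1")
        names = [g for p in self.pathways for g in p.genes]
        if len(names) != len(set(names)):
            raise ValueError("gene names must be unique across pathways")

    def to_json(self) -> str:
        d = {
            "n_metabolites": self.n_metabolites,
            "pathways": [
                {"name": p.name, "genes": list(p.genes),
                 "base_signature": list(p.base_signature) if p.base_signature else None}
                for p in self.pathways
            ],
            "responding_fraction": self.responding_fraction,
            "base_sd": self.base_sd,
            "gene_offset_sd": self.gene_offset_sd,
            "severity_range": list(self.severity_range),
            "noise_sd": self.noise_sd,
            "alleles_per_gene": self.alleles_per_gene,
            "seed": self.seed,
            "coupled_genes": list(self.coupled_genes) if self.coupled_genes else None,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimScenario":
        d = json.loads(text)
        d["pathways"] = tuple(
            PathwaySpec(
                name=p["name"], genes=tuple(p["genes"]),
                base_signature=tuple(p["base_signature"]) if p.get("base_signature") else None,
            )
            for p in d["pathways"]
        )
        d["severity_range"] = tuple(d["severity_range"])
        if d.get("coupled_genes"):
            d["coupled_genes"] = tuple(d["coupled_genes"])
        return cls(**d)


def default_scenario(seed: int = 0, **overrides) -> SimScenario:
    """13 genes in 4 pathways (4/4/3/2), 2 alleles per gene — 26 mutant
    phenotypes over a 100-metabolite metabolome, mirroring a 13-query /
    13-reference panel spanning one metabolic pathway's steps."""
    pathways = (
        PathwaySpec("pw1", ("g01", "g02", "g03", "g04")),
        PathwaySpec("pw2", ("g05", "g06", "g07", "g08")),
        PathwaySpec("pw3", ("g09", "g10", "g11")),
        PathwaySpec("pw4", ("g12", "g13")),
    )
    return SimScenario(pathways=pathways, seed=seed, **overrides)


def coupled_scenario(seed: int = 0, **overrides) -> SimScenario:
    """The default scenario with two genes of pathway 1 biochemically
    coupled (identical signatures) — the hard discrimination case where
    directional overlap alone cannot separate the genes."""
    return default_scenario(seed=seed, coupled_genes=("g01", "g02"), **overrides)


def _metabolite_key(i: int, width: int) -> MetaboliteKey:
    return MetaboliteKey(f"m{i:0{width}d}", known=False)


def generate_library(
    sc: SimScenario,
) -> tuple[list[Phenotype], dict[str, str], dict[str, str]]:
    """Generate the mutant phenotype library for a scenario.

    Returns ``(phenotypes, truth, pathway_map)`` where ``truth`` maps
    phenotype id -> causal gene and ``pathway_map`` maps gene -> pathway.
    Phenotype ids are ``<gene>-a<k>`` for allele k.  Fully deterministic
    under the scenario seed.
    """
    rng = np.random.default_rng(sc.seed)
    width = len(str(sc.n_metabolites - 1))
    keys = [_metabolite_key(i, width) for i in range(sc.n_metabolites)]
    n_resp = max(1, round(sc.responding_fraction * sc.n_metabolites))

    gene_signatures: dict[str, np.ndarray] = {}
    pathway_map: dict[str, str] = {}
    for pw in sc.pathways:
        if pw.base_signature is not None:
            if len(pw.base_signature) != sc.n_metabolites:
                raise ValueError(
                    f"pathway {pw.name!r}: base_signature length "
                    f"{len(pw.base_signature)} != n_metabolites {sc.n_metabolites}"
                )
            base = np.asarray(pw.base_signature, dtype=float)
            responding = np.flatnonzero(base)
        else:
            responding = rng.choice(sc.n_metabolites, size=n_resp, replace=False)
            base = np.zeros(sc.n_metabolites)
            base[responding] = rng.normal(0.0, sc.base_sd, size=n_resp)
        for gene in pw.genes:
            offsets = np.zeros(sc.n_metabolites)
            if responding.size:
                offsets[responding] = rng.normal(
                    0.0, sc.gene_offset_sd, size=responding.size
                )
            gene_signatures[gene] = base + offsets
            pathway_map[gene] = pw.name

    if sc.coupled_genes is not None:
        g1, g2 = sc.coupled_genes
        if g1 not in gene_signatures or g2 not in gene_signatures:
            raise ValueError(f"coupled_genes {sc.coupled_genes} not in scenario")
        gene_signatures[g2] = gene_signatures[g1].copy()
        logger.info("generate_library: coupled genes %s share one signature", sc.coupled_genes)

    phenotypes: list[Phenotype] = []
    truth: dict[str, str] = {}
    lo, hi = sc.severity_range
    for gene in sorted(gene_signatures):
        sig = gene_signatures[gene]
        for k in range(sc.alleles_per_gene):
            severity = rng.uniform(lo, hi)
            eps = rng.normal(0.0, sc.noise_sd, size=sc.n_metabolites)
            sirs = np.exp(severity * sig + eps)
            pid = f"{gene}-a{k + 1}"
            phenotypes.append(
                Phenotype(
                    id=pid,
                    responses={keys[i]: float(sirs[i]) for i in range(sc.n_metabolites)},
                    metadata={
                        "gene": gene,
                        "pathway": pathway_map[gene],
                        "severity": f"{severity:.6f}",
                        "synthetic": "true",
                    },
                )
            )
            truth[pid] = gene
    return phenotypes, truth, pathway_map


def inject_platform_bias(
    phenotypes: Sequence[Phenotype], coverage_fraction: float, seed: int = 0
) -> list[Phenotype]:
    """Randomly mask (1 - coverage_fraction) of each phenotype's metabolites,
    simulating analytical platforms with differing metabolome coverage."""
    if not 0.0 < coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must be in (0, 1]")
    if coverage_fraction == 1.0:
        return list(phenotypes)
    rng = np.random.default_rng(seed)
    masked = []
    for p in phenotypes:
        keys = sorted(p.responses)
        keep = rng.random(len(keys)) < coverage_fraction
        responses = {k: p.responses[k] for k, kept in zip(keys, keep) if kept}
        meta = dict(p.metadata)
        meta["coverage_fraction"] = f"{coverage_fraction:.4f}"
        masked.append(Phenotype(id=p.id, responses=responses, metadata=meta))
    return masked


def write_library(
    sc: SimScenario,
    out_dir: str | Path,
) -> tuple[list[Phenotype], dict[str, str], dict[str, str]]:
    """Generate a library and write it to disk: one phenotype TSV per mutant,
    a ``truth.tsv`` (phenotype_id, gene_id, pathway_id), and the scenario as
    ``scenario.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phenotypes, truth, pathway_map = generate_library(sc)
    lib_dir = out_dir / "library"
    lib_dir.mkdir(exist_ok=True)
    for p in phenotypes:
        write_phenotype(p, lib_dir / f"{p.id}.tsv")
    with open(out_dir / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("phenotype_id\tgene_id\tpathway_id\n")
        for pid in sorted(truth):
            gene = truth[pid]
            fh.write(f"{pid}\t{gene}\t{pathway_map[gene]}\n")
    (out_dir / "scenario.json").write_text(sc.to_json() + "\n", encoding="utf-8")
    return phenotypes, truth, pathway_map
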