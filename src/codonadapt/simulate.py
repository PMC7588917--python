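"""Synthetic inputs with known ground truth: tRNA pools, codon-biased CDS,
and two-condition expression tables.

The generator emulates the three inputs of the real study design — a fungal
tRNA gene complement with heterogeneous copy numbers, coding sequences whose
synonymous-codon choice is biased toward high-adaptiveness codons, and a
glucose-vs-wood expression table in which the induced subset is enriched for
well-adapted genes — so every pipeline stage is testable without downloads.

Codon choice is a softmax in the adaptiveness weight: within its synonymous
family, codon c is drawn with probability proportional to exp(beta_g * w_c),
where beta_g >= 0 is the gene's selection strength. beta = 0 gives uniform
synonymous usage; large beta approaches all-optimal codons. This is the
simplest mechanism that makes CAI, Nc, tAI, AAtAI and CPB all respond
monotonically to one knob, which is exactly what the parameter-recovery
tests need; it is a modeling convenience, not a claim about any genome.

Everything is driven by one ``numpy.random.default_rng(seed)``; a fixed seed
reproduces byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adaptiveness import AdaptivenessVector, compute_wi, default_wobble_rules
from .cds import CodingSequence
from .genetic_code import anticodon_to_codon, codon_to_anticodon, standard_code
from .trna import TRNAGene, TRNAGeneSet, write_trnascan


class SimulationConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the generator; serialized alongside every output set."""

    seed: int = 0
    # CDS corpus
    n_genes: int = 2000
    len_min: int = 100          # codons
    len_mean: int = 350
    len_max: int = 2000
    beta_shape: float = 0.8     # per-gene selection strength ~ Gamma(shape, scale):
    beta_scale: float = 5.0     # L-shaped, most genes weakly selected, long strong tail
    # tRNA pool
    anticodon_presence: float = 0.5   # P(non-mandatory WC anticodon present)
    tgcn_nb_n: float = 1.2            # extra copies ~ NegBin(n, p): long-tailed
    tgcn_nb_p: float = 0.3
    n_scaffolds: int = 30
    intron_fraction: float = 0.72
    # expression table
    induced_fraction: float = 0.15
    repressed_fraction: float = 0.075
    top_quantile: float = 1.0 / 3.0   # induced genes drawn from this top-beta slice
    induced_effect_min: float = 1.0   # log2 units (>= twofold)
    induced_effect_mean_excess: float = 1.0
    noise_sd: float = 0.25
    sig_p_log10_range: tuple[float, float] = (-6.0, -1.4)  # p ~ 10^U(range)
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.induced_fraction < 1.0:
            raise SimulationConfigError("induced_fraction must be in [0, 1)")
        if not 0.0 <= self.repressed_fraction < 1.0:
            raise SimulationConfigError("repressed_fraction must be in [0, 1)")
        if self.induced_fraction > self.top_quantile:
            raise SimulationConfigError(
                "induced_fraction cannot exceed top_quantile (not enough top-beta genes)"
            )
        if self.induced_fraction + self.repressed_fraction >= 1.0:
            raise SimulationConfigError("induced + repressed fractions must sum below 1")
        if not (1 <= self.len_min <= self.len_mean <= self.len_max):
            raise SimulationConfigError("need len_min <= len_mean <= len_max, all >= 1")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sig_p_log10_range"] = list(self.sig_p_log10_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SimulationConfigError(f"unknown config keys: {sorted(unknown)}")
        if "sig_p_log10_range" in data:
            data["sig_p_log10_range"] = tuple(data["sig_p_log10_range"])
        return cls(**data)


def simulate_trna_pool(config: SimulationConfig, rng: np.random.Generator) -> TRNAGeneSet:
    """Draw a tRNA gene set with long-tailed copy numbers.

    Every synonymous family gets the Watson–Crick anticodon of one of its
    codons (coverage guarantee); each remaining WC anticodon is present with
    probability ``anticodon_presence``. Copies per present anticodon are
    1 + NegBin(n, p), a skewed distribution that reproduces the observed
    many-copies-for-few-anticodons shape of real fungal pools.
    """
    config.validate()
    code = standard_code()
    anticodons: list[str] = []
    for family in code.families.values():
        fam = list(family)
        mandatory = fam[int(rng.integers(len(fam)))]
        for codon in fam:
            if codon == mandatory or rng.random() < config.anticodon_presence:
                anticodons.append(codon_to_anticodon(codon))

    genes: list[TRNAGene] = []
    cursors = {i: 1000 for i in range(1, config.n_scaffolds + 1)}
    idx_per_scaffold: dict[int, int] = {}
    for anticodon in anticodons:
        tgcn = 1 + int(rng.negative_binomial(config.tgcn_nb_n, config.tgcn_nb_p))
        for _ in range(tgcn):
            scaffold_i = int(rng.integers(1, config.n_scaffolds + 1))
            begin = cursors[scaffold_i]
            cursors[scaffold_i] += int(rng.integers(2000, 20000))
            has_intron = rng.random() < config.intron_fraction
            idx_per_scaffold[scaffold_i] = idx_per_scaffold.get(scaffold_i, 0) + 1
            genes.append(
                TRNAGene(
                    scaffold=f"scaffold_{scaffold_i}",
                    index=idx_per_scaffold[scaffold_i],
                    isotype=code.translate(anticodon_to_codon(anticodon)),
                    anticodon=anticodon,
                    begin=begin,
                    end=begin + 71,
                    intron_begin=begin + 37 if has_intron else 0,
                    intron_end=begin + 47 if has_intron else 0,
                    score=float(np.round(rng.uniform(40, 80), 1)),
                )
            )
    geneset = TRNAGeneSet(genes=genes)

    # coverage check: every family must end up decodable with positive weight
    adapt_probe = compute_wi(geneset, default_wobble_rules())
    for aa, family in code.families.items():
        if max(adapt_probe.W[c] for c in family) == 0:
            raise SimulationConfigError(f"tRNA pool leaves amino acid {aa} uncovered")
    return geneset


def simulate_cds(
    config: SimulationConfig,
    adapt: AdaptivenessVector,
    rng: np.random.Generator,
) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Generate codon-biased coding sequences with per-gene true beta.

    Amino acids are i.i.d. uniform (after a fixed Met start); within each
    family the codon is drawn with probability proportional to
    exp(beta_g * w_c). Returns the genes plus a ground-truth frame
    (id, beta, length).
    """
    config.validate()
    code = standard_code()
    families = {aa: list(fam) for aa, fam in code.families.items()}
    for aa, fam in families.items():
        if not any(adapt.w[c] > 0 for c in fam):
            raise SimulationConfigError(f"adaptiveness vector empty for family {aa}")
    aa_list = sorted(families)
    w_by_family = {aa: np.array([adapt.w[c] for c in fam]) for aa, fam in families.items()}

    # length ~ Gamma matched to (mean - min), shifted, clipped to [min, max]
    shape = 3.0
    scale = max((config.len_mean - config.len_min) / shape, 1e-9)
    lengths = config.len_min + rng.gamma(shape, scale, size=config.n_genes)
    lengths = np.clip(np.round(lengths), config.len_min, config.len_max).astype(int)
    betas = rng.gamma(config.beta_shape, config.beta_scale, size=config.n_genes)

    genes: list[CodingSequence] = []
    rows = []
    for g in range(config.n_genes):
        gene_id = f"gene_{g + 1:05d}"
        length = int(lengths[g])
        beta = float(betas[g])
        aas = rng.choice(aa_list, size=length - 1)
        codons = np.empty(length, dtype=object)
        codons[0] = "ATG"
        # draw codons family-by-family under the softmax bias
        for aa in np.unique(aas):
            pos = np.nonzero(aas == aa)[0] + 1
            fam = families[aa]
            logits = beta * w_by_family[aa]
            probs = np.exp(logits - logits.max())
            probs /= probs.sum()
            codons[pos] = rng.choice(fam, size=len(pos), p=probs)
        genes.append(CodingSequence(id=gene_id, codons=tuple(codons.tolist())))
        rows.append({"id": gene_id, "beta": beta, "length": length})
    return genes, pd.DataFrame(rows)


def simulate_expression(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Two-condition expression table with an induced, high-beta-enriched subset.

    Induced genes are sampled uniformly from the top ``top_quantile`` slice of
    true beta and get a log2 effect >= ``induced_effect_min`` with a small
    p-value; repressed genes are beta-independent with the mirrored effect;
    background genes get Normal(0, noise_sd) effects and Uniform(0, 1)
    p-values, so the expected C/D split is analytic (alpha vs 1 - alpha).
    """
    config.validate()
    n = len(truth)
    ids = truth["id"].to_numpy()
    beta = truth["beta"].to_numpy(dtype=float)

    n_induced = int(round(config.induced_fraction * n))
    n_repressed = int(round(config.repressed_fraction * n))
    order = np.argsort(beta)[::-1]  # descending beta
    top_pool = order[: max(int(math.ceil(config.top_quantile * n)), n_induced)]
    induced_idx = rng.choice(top_pool, size=n_induced, replace=False) if n_induced else np.array([], dtype=int)
    remaining = np.setdiff1d(np.arange(n), induced_idx)
    repressed_idx = (
        rng.choice(remaining, size=n_repressed, replace=False) if n_repressed else np.array([], dtype=int)
    )

    glu = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    effect = rng.normal(0.0, config.noise_sd, size=n)
    p = rng.uniform(0.0, 1.0, size=n)

    lo, hi = config.sig_p_log10_range
    if len(induced_idx):
        effect[induced_idx] = config.induced_effect_min + rng.exponential(
            config.induced_effect_mean_excess, size=len(induced_idx)
        )
        p[induced_idx] = 10.0 ** rng.uniform(lo, hi, size=len(induced_idx))
    if len(repressed_idx):
        effect[repressed_idx] = -(
            config.induced_effect_min
            + rng.exponential(config.induced_effect_mean_excess, size=len(repressed_idx))
        )
        p[repressed_idx] = 10.0 ** rng.uniform(lo, hi, size=len(repressed_idx))

    status = np.full(n, "background", dtype=object)
    status[induced_idx] = "induced"
    status[repressed_idx] = "repressed"

    return pd.DataFrame(
        {
            "id": ids,
            "log2_glucose": np.round(glu, 4),
            "log2_bma": np.round(glu + effect, 4),
            "p_value": p,
            "true_status": status,
        }
    )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    trna: TRNAGeneSet
    adapt: AdaptivenessVector
    genes: list[CodingSequence]
    truth: pd.DataFrame
    expression: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def simulate_all(config: SimulationConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    """Run the full generator; optionally write the file set to ``outdir``.

    Files written: ``cds.fasta`` (with terminal stop codons, as real CDS
    carry), ``trna.tsv`` (tRNAscan-SE layout), ``expression.tsv``,
    ``truth.tsv`` and ``config.yaml``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    trna = simulate_trna_pool(config, rng)
    adapt = compute_wi(trna, default_wobble_rules())
    genes, truth = simulate_cds(config, adapt, rng)
    expression = simulate_expression(config, truth, rng)

    dataset = SimulatedDataset(
        config=config, trna=trna, adapt=adapt, genes=genes, truth=truth, expression=expression
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stops = ("TAA", "TAG", "TGA")
        with open(outdir / "cds.fasta", "w") as fh:
            for g in genes:
                seq = g.sequence + stops[int(rng.integers(3))]
                fh.write(f">{g.id}\n")
                fh.write("\n".join(seq[i : i + 60] for i in range(0, len(seq), 60)) + "\n")
        write_trnascan(trna, outdir / "trna.tsv")
        expression.drop(columns=["true_status"]).to_csv(
            outdir / "expression.tsv", sep="\t", index=False
        )
        truth.merge(expression[["id", "true_status"]], on="id").to_csv(
            outdir / "truth.tsv", sep="\t", index=False
        )
        config.to_yaml(outdir / "config.yaml")
        dataset.paths = {
            "cds": outdir / "cds.fasta",
            "trna": outdir / "trna.tsv",
            "expression": outdir / "expression.tsv",
            "truth": outdir / "truth.tsv",
            "config": outdir / "config.yaml",
        }
    return dataset
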