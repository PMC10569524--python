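"""Seeded generators for every input the pipeline consumes.

The generator emulates a two-genotype (WT vs heterozygous mutant), two-sex
perinatal brain single-cell experiment: negative-binomial counts with
mean-dependent dropout, planted log2 fold changes concentrated in one
"vulnerable" cell population, a compound reference library containing planted
reversers and mimics of the disease signature, per-gene CLIP binding-site
intervals with one high-density gene, and longitudinal two-group phenotype
measurements.  Identical seeds yield bit-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import ConfigError, SimConfig

GENOTYPES = ("WT", "HET")


@dataclass
class SimTruth:
    """Ground truth of the simulation, for parameter-recovery tests.

    effects: one row per planted (gene, cell_type) pair with its true log2FC;
    pairs absent from the table have a true effect of exactly zero.
    """

    effects: pd.DataFrame
    compound_roles: pd.DataFrame = field(default_factory=pd.DataFrame)
    phenotype_shifts: dict = field(default_factory=dict)
    clip_enriched_gene: str | None = None

    def true_log2fc(self, gene: str, cell_type: str) -> float:
        m = (self.effects["gene"] == gene) & (self.effects["cell_type"] == cell_type)
        if not m.any():
            return 0.0
        return float(self.effects.loc[m, "true_log2fc"].iloc[0])

    def planted_genes(self, cell_type: str) -> pd.DataFrame:
        return self.effects[self.effects["cell_type"] == cell_type]


def _gene_ids(n: int) -> list[str]:
    # zero-padded ids make lexicographic tie-breaking deterministic
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def make_gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Per-gene annotation shared by all generators for one config.

    Columns: gene (index), is_mito, length_bp, exclude_class (non-coding /
    ribosomal / pseudogene proxy), has_homolog, and one boolean column per
    disease gene set.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    ids = _gene_ids(config.n_genes)
    n = config.n_genes
    is_mito = np.zeros(n, dtype=bool)
    is_mito[: config.n_mito_genes] = True
    length_bp = np.maximum(
        200,
        rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd, n).astype(int),
    )
    exclude_class = rng.random(n) < config.frac_excluded_class
    exclude_class[is_mito] = False
    has_homolog = rng.random(n) < config.frac_has_homolog
    meta = pd.DataFrame(
        {
            "is_mito": is_mito,
            "length_bp": length_bp,
            "exclude_class": exclude_class,
            "has_homolog": has_homolog,
        },
        index=pd.Index(ids, name="gene"),
    )
    return meta


def _plant_effects(config: SimConfig, gene_meta: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Choose planted (gene, cell_type) log2 fold changes.

    The vulnerable population receives frac_de_vulnerable of eligible genes,
    every other population frac_de_other; effect magnitudes are
    Normal(lfc_mean, lfc_sd) truncated at zero, with sign negative with
    probability down_bias.
    """
    eligible = gene_meta.index[~gene_meta["is_mito"] & ~gene_meta["exclude_class"]]
    eligible = np.asarray(eligible)
    rows = []
    for ct in config.cell_type_labels():
        frac = (config.frac_de_vulnerable if ct == config.vulnerable_type
                else config.frac_de_other)
        k = int(round(frac * len(eligible)))
        if k == 0:
            continue
        genes = rng.choice(eligible, size=k, replace=False)
        mag = np.abs(rng.normal(config.lfc_mean, config.lfc_sd, k))
        mag = np.maximum(mag, 1e-3)
        sign = np.where(rng.random(k) < config.down_bias, -1.0, 1.0)
        for g, s, m in zip(genes, sign, mag):
            rows.append((g, ct, s * m))
    eff = pd.DataFrame(rows, columns=["gene", "cell_type", "true_log2fc"])
    return eff.sort_values(["cell_type", "gene"]).reset_index(drop=True)


def _assign_disease_sets(config: SimConfig, gene_meta: pd.DataFrame,
                         effects: pd.DataFrame, rng: np.random.Generator) -> None:
    """Disease gene sets sampled with extra weight on genes planted down in the
    vulnerable population, so enrichment recovery is exercised end to end."""
    down_vuln = set(
        effects.loc[(effects["cell_type"] == config.vulnerable_type)
                    & (effects["true_log2fc"] < 0), "gene"]
    )
    candidates = gene_meta.index[gene_meta["has_homolog"]
                                 & ~gene_meta["is_mito"]
                                 & ~gene_meta["exclude_class"]]
    weights = np.where(np.isin(candidates, list(down_vuln)),
                       config.disease_set_enrichment, 1.0)
    weights = weights / weights.sum()
    for name in config.disease_set_names:
        size = min(config.disease_set_size, len(candidates))
        chosen = rng.choice(candidates, size=size, replace=False, p=weights)
        col = np.zeros(len(gene_meta), dtype=bool)
        col[gene_meta.index.get_indexer(chosen)] = True
        gene_meta[f"set_{name}"] = col


def simulate_counts(config: SimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Generate the annotated count matrix and its ground truth.

    Counts are NB(mean, dispersion) per gene with the genotype effect
    2**true_log2fc applied to mutant means in affected (gene, cell_type)
    pairs, then thinned by Bernoulli dropout whose logit is linear in the
    log mean.  A designated mitochondrial gene block yields per-cell
    mitochondrial fractions inside ``mito_fraction_range``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 202]))
    gene_meta = make_gene_annotation(config)
    effects = _plant_effects(config, gene_meta, rng)
    _assign_disease_sets(config, gene_meta, effects, rng)

    n_genes = config.n_genes
    labels = config.cell_type_labels()
    n_per = config.cells_per_type_per_genotype
    n_cells = len(labels) * len(GENOTYPES) * n_per

    base_mean = np.exp(rng.uniform(np.log(config.baseline_mean_range[0]),
                                   np.log(config.baseline_mean_range[1]), n_genes))
    dispersion = np.exp(rng.uniform(np.log(config.dispersion_range[0]),
                                    np.log(config.dispersion_range[1]), n_genes))

    cell_type = np.repeat(labels, len(GENOTYPES) * n_per)
    genotype = np.tile(np.repeat(GENOTYPES, n_per), len(labels))
    sex = np.where(rng.random(n_cells) < config.sex_ratio, "F", "M")
    size_factor = rng.lognormal(0.0, config.cell_size_sd, n_cells)

    # per-cell mean matrix: baseline x size factor x genotype effect
    log2fc = np.zeros((n_genes, len(labels)))
    gene_pos = pd.Series(np.arange(n_genes), index=gene_meta.index)
    ct_pos = {ct: j for j, ct in enumerate(labels)}
    for _, row in effects.iterrows():
        log2fc[gene_pos[row["gene"]], ct_pos[row["cell_type"]]] = row["true_log2fc"]

    mean = base_mean[:, None] * size_factor[None, :]
    het = genotype == "HET"
    for j, ct in enumerate(labels):
        cols = (cell_type == ct) & het
        if cols.any():
            mean[:, cols] *= np.exp2(log2fc[:, j])[:, None]

    # NB draw: numpy parameterization n=dispersion r, p = r/(r+mean)
    r = dispersion[:, None]
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p).astype(np.int32)

    # logistic dropout: P(drop) = sigmoid(-slope * (log mean - midpoint))
    with np.errstate(divide="ignore"):
        logmean = np.log(np.maximum(mean, 1e-12))
    p_drop = 1.0 / (1.0 + np.exp(config.dropout_slope * (logmean - config.dropout_midpoint)))
    counts[rng.random(counts.shape) < p_drop] = 0

    # mitochondrial block: per-cell target fraction drawn inside the range
    mito_idx = np.flatnonzero(gene_meta["is_mito"].to_numpy())
    counts[mito_idx, :] = 0
    nonmito_total = counts.sum(axis=0)
    lo, hi = config.mito_fraction_range
    target = rng.uniform(lo, hi, n_cells)
    mito_total = np.round(target / (1.0 - target) * nonmito_total).astype(np.int64)
    probs = np.full(len(mito_idx), 1.0 / len(mito_idx))
    for c in range(n_cells):
        if mito_total[c] > 0:
            counts[mito_idx, c] = rng.multinomial(mito_total[c], probs)

    X = sp.csr_matrix(counts.T)  # cells x genes
    obs = pd.DataFrame(
        {
            "genotype": pd.Categorical(genotype, categories=list(GENOTYPES)),
            "sex": pd.Categorical(sex, categories=["M", "F"]),
            "cell_type": pd.Categorical(cell_type, categories=labels),
            "region": config.region,
        },
        index=pd.Index([f"cell{i:06d}" for i in range(1, n_cells + 1)], name="barcode"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=gene_meta.copy())
    adata.uns["sim_seed"] = int(config.seed)

    truth = SimTruth(
        effects=effects,
        phenotype_shifts={m: spec["het_shift"]
                          for m, spec in config.phenotype_measures.items()},
        clip_enriched_gene=config.clip_enriched_gene or gene_meta.index[-1],
    )
    return adata, truth


def simulate_reference_signatures(
    config: SimConfig, disease_signature: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compound reference library of differential-expression z-scores.

    ``disease_signature`` is a per-gene signed effect vector (e.g. the true or
    estimated log2FC profile).  Planted reversers are its negation plus
    Gaussian noise, mimics its copy plus noise, and the remaining compounds
    independent standard normals.  Returns (z, compound_meta) where z is a
    genes x compounds DataFrame.
    """
    config.validate()
    if config.n_planted_reversers + config.n_planted_mimics > config.n_compounds:
        raise ConfigError("planted reversers + mimics exceed n_compounds")
    disease_signature = disease_signature.astype(float)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 303]))
    genes = disease_signature.index
    n_g = len(genes)
    n_c = config.n_compounds
    width = max(4, len(str(n_c)))
    compounds = [f"cmpd{i:0{width}d}" for i in range(1, n_c + 1)]

    roles = np.array(["null"] * n_c, dtype=object)
    roles[: config.n_planted_reversers] = "reverser"
    roles[config.n_planted_reversers:
          config.n_planted_reversers + config.n_planted_mimics] = "mimic"

    classes = np.array(["inert"] * n_c, dtype=object)
    classes[roles == "reverser"] = "planted_reverser_class"
    classes[roles == "mimic"] = "planted_mimic_class"

    z = rng.standard_normal((n_g, n_c))
    vec = disease_signature.to_numpy()
    for j in range(n_c):
        if roles[j] == "reverser":
            z[:, j] = -vec + rng.normal(0.0, config.signature_noise_sd, n_g)
        elif roles[j] == "mimic":
            z[:, j] = vec + rng.normal(0.0, config.signature_noise_sd, n_g)

    zdf = pd.DataFrame(z, index=pd.Index(genes, name="gene"), columns=compounds)
    meta = pd.DataFrame({"compound": compounds, "role": roles, "class": classes}
                        ).set_index("compound")
    return zdf, meta


def simulate_clip_sites(gene_annotation: pd.DataFrame,
                        config: SimConfig) -> pd.DataFrame:
    """Per-gene binding-site intervals (BED-style, 0-based half-open).

    Site counts are Poisson(clip_lambda * length_kb); the designated enriched
    gene draws at ``clip_enrichment * clip_lambda + clip_enriched_floor`` sites
    per kb so its length-normalized density exceeds the 99th percentile.
    """
    config.validate()
    if "length_bp" not in gene_annotation.columns:
        raise ValueError("gene annotation must carry a length_bp column")
    lengths = gene_annotation["length_bp"]
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("all gene lengths must be present and positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 404]))
    enriched = config.clip_enriched_gene or gene_annotation.index[-1]
    if enriched not in gene_annotation.index:
        raise ValueError(f"enriched gene {enriched!r} absent from annotation")

    rate_kb = np.full(len(gene_annotation), float(config.clip_lambda))
    pos = gene_annotation.index.get_loc(enriched)
    rate_kb[pos] = config.clip_enrichment * config.clip_lambda + config.clip_enriched_floor
    lam = rate_kb * lengths.to_numpy() / 1000.0
    n_sites = rng.poisson(lam)

    rows = []
    for gene, length, k in zip(gene_annotation.index, lengths.to_numpy(), n_sites):
        if k == 0:
            continue
        width = min(config.clip_site_width, int(length))
        starts = np.sort(rng.integers(0, max(1, length - width + 1), size=k))
        for s in starts:
            rows.append((gene, int(s), int(min(s + width, length))))
    return pd.DataFrame(rows, columns=["gene", "start", "end"])


def simulate_phenotypes(config: SimConfig) -> pd.DataFrame:
    """Long-format subject x timepoint x measure table.

    The mutant group receives the configured additive shift per measure;
    latency measures are clipped to their [min_value, cutoff] bounds (failed
    trials saturate at the cutoff, matching a 30 s latency ceiling).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 505]))
    n = config.n_subjects_per_genotype
    subjects = [(f"{gt.lower()}{i:03d}", gt)
                for gt in GENOTYPES for i in range(1, n + 1)]
    sexes = {sid: ("F" if rng.random() < config.sex_ratio else "M")
             for sid, _ in subjects}
    rows = []
    for measure, spec in config.phenotype_measures.items():
        cutoff = spec.get("cutoff")
        min_value = spec.get("min_value")
        for tp, base in zip(spec["timepoints"], spec["baseline"]):
            for sid, gt in subjects:
                val = base + rng.normal(0.0, spec["sd"])
                if gt == "HET":
                    val += spec["het_shift"]
                if min_value is not None:
                    val = max(val, min_value)
                if cutoff is not None:
                    val = min(val, cutoff)
                rows.append((sid, gt, sexes[sid], tp, measure, val,
                             cutoff if cutoff is not None else np.nan))
    return pd.DataFrame(
        rows, columns=["subject", "genotype", "sex", "timepoint",
                       "measure", "value", "cutoff"])


def amplicon_sizes(wt_product_bp: int, deletion_bp: int) -> int:
    """Mutant PCR product size for a deletion allele.

    A deletion inside the amplified region shortens the product by exactly the
    deleted length (e.g. a 745-bp wild-type product with a 113-bp deletion
    yields a 632-bp mutant product).
    """
    if deletion_bp < 0 or wt_product_bp <= 0:
        raise ValueError("sizes must be nonnegative and product positive")
    if deletion_bp >= wt_product_bp:
        raise ValueError("deletion must be smaller than the wild-type product")
    return int(wt_product_bp) - int(deletion_bp)
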