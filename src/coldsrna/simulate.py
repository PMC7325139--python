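"""Synthetic cold-acclimation data with known ground truth.

Generates locus catalogs, mature-miRNA and transcript sequences,
negative-binomial count matrices for a 2-condition x 3-time-point x
3-replicate design, tiered regulatory edge tables, and regulator-driven
target expression -- everything the downstream stages consume, with a
truth record for each planted effect.

Statistical model
-----------------
Counts are NB(mean = s_j * q_i * 2^(beta * x), Var = mu + alpha * mu^2)
where s_j is a log-normal library-size factor, q_i a log-normal feature
base mean, beta a planted log2 fold change active only in cold samples
at the planted time point, and alpha a per-feature dispersion drawn
log-uniform from [0.01, 0.5] (a typical bulk RNA-seq overdispersion
range) unless fixed in the config.

Planted structure:

* a fraction ``de_fraction`` of features is differentially expressed at
  one random time point with signed log2FC ``de_log2fc``;
* each miRNA has one target transcript embedding a (near-)reverse-
  complementary site; if the miRNA is planted DE, the target's cold mean
  is scaled by 2^(-coupling_strength * beta) (anticorrelation);
* half of the cis-NAT pairs are planted as classical nat-siRNA regulons:
  driver transcript up, partner transcript down, and the pair's siRNA
  cluster up, all at one time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import Feature, LocusCatalog

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "cold")
TIME_POINTS = ("3h", "6h", "2d")

_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.replace("U", "T").translate(_RC)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study (defaults emulate the assumed design)."""

    n_mirna: int = 30
    n_tf: int = 20
    n_targets: int = 120
    n_cis_nat_pairs: int = 12
    n_trans_nat_pairs: int = 10
    n_lncrna: int = 10
    n_replicates: int = 3
    library_size_mean: float = 1e6
    nb_dispersion: Optional[float] = None  # None -> per-feature log-uniform [0.01, 0.5]
    de_fraction: float = 0.15
    de_log2fc: float = 2.0
    coupling_strength: float = 0.8
    edge_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirna", "n_tf", "n_targets", "n_cis_nat_pairs",
                     "n_trans_nat_pairs", "n_lncrna", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.de_fraction < 1):
            raise ValueError("de_fraction must lie in [0, 1)")
        if self.de_log2fc < 1:
            raise ValueError("de_log2fc must be >= 1")
        if not (0 <= self.coupling_strength <= 1):
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.edge_noise_sd < 0:
            raise ValueError("edge_noise_sd must be >= 0")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be > 0")

    def samples(self) -> pd.DataFrame:
        rows = [
            {"sample": f"{cond}_{tp}_r{rep}", "condition": cond, "time": tp,
             "replicate": str(rep)}
            for tp in TIME_POINTS
            for cond in CONDITIONS
            for rep in range(1, self.n_replicates + 1)
        ]
        return pd.DataFrame(rows)

    def _rng(self, stream: int) -> np.random.Generator:
        # all substreams derive deterministically from the one global seed
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SyntheticTruth:
    """Ground-truth record for one simulation."""

    de_features: set[tuple[str, str, float]] = field(default_factory=set)
    planted_target_pairs: set[tuple[str, str, str]] = field(default_factory=set)
    planted_regulons: set[tuple[str, str, str, str]] = field(default_factory=set)
    functional_edges: set[tuple[str, str, float]] = field(default_factory=set)
    noise_sd: Optional[float] = None

    def to_records(self) -> dict[str, list[str]]:
        rec: dict[str, list[str]] = {}
        rec["de_feature"] = sorted(
            f"{f}\t{t}\t{lfc:.6g}" for f, t, lfc in self.de_features)
        rec["target_pair"] = sorted(
            f"{m}\t{g}\t{c}" for m, g, c in self.planted_target_pairs)
        rec["regulon"] = sorted(
            f"{p}\t{d}\t{q}\t{t}" for p, d, q, t in self.planted_regulons)
        rec["functional_edge"] = sorted(
            f"{r}\t{g}\t{w:.6g}" for r, g, w in self.functional_edges)
        if self.noise_sd is not None:
            rec["noise_sd"] = [f"{self.noise_sd:.6g}"]
        return rec


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def generate_catalog(config: SimulationConfig) -> tuple[LocusCatalog, dict[str, str]]:
    """Emit the locus catalog and the sequence collection.

    Each cis-NAT pair is two overlapping features on opposite strands; each
    trans-NAT pair is two non-overlapping partner-linked features; each
    miRNA carries a 20-24 nt mature sequence whose (near-)reverse
    complement is embedded in its planted target transcript with 0-2
    mismatches outside the seed region.
    """
    rng = config._rng(0)
    features: list[Feature] = []
    sequences: dict[str, str] = {}
    cursor = 1000

    def place(length: int, gap: int = 500) -> tuple[int, int]:
        nonlocal cursor
        start = cursor
        cursor += length + gap
        return start, start + length

    mirna_ids = [f"miR{i + 1:04d}" for i in range(config.n_mirna)]
    for i, mid in enumerate(mirna_ids):
        start, end = place(120)
        family = f"miRF{i // 2 + 1:03d}"
        features.append(Feature(mid, "chr1", start, end, "+", "miRNA", family=family))
        sequences[mid] = _random_seq(rng, int(rng.integers(20, 25)))

    target_ids = [f"GENE{i + 1:04d}" for i in range(config.n_targets)]
    planted_sites: dict[str, tuple[str, int]] = {}
    for i, gid in enumerate(target_ids):
        start, end = place(500)
        features.append(Feature(gid, "chr1", start, end, "+", "other"))
        seq = _random_seq(rng, 500)
        if i < config.n_mirna:
            mid = mirna_ids[i]
            site = reverse_complement(sequences[mid])
            n_mm = int(rng.integers(0, 3))
            site = _mutate_outside_seed(site, len(sequences[mid]), n_mm, rng)
            offset = int(rng.integers(50, 500 - len(site) - 50))
            seq = seq[:offset] + site + seq[offset + len(site):]
            planted_sites[gid] = (mid, offset)
        sequences[gid] = seq

    for i in range(config.n_tf):
        tid = f"TF{i + 1:04d}"
        start, end = place(500)
        features.append(Feature(tid, "chr1", start, end, "+", "other",
                                family=f"TFfam{i % min(6, config.n_tf) + 1:02d}"))
        sequences[tid] = _random_seq(rng, 500)

    for i in range(config.n_cis_nat_pairs):
        pid = f"CIS{i + 1:03d}"
        a_start, a_end = place(400, gap=0)
        b_start, b_end = a_start + 200, a_start + 600
        cursor = b_end + 500
        features.append(Feature(f"{pid}a", "chr1", a_start, a_end, "+", "cis_NAT",
                                partner_id=f"{pid}b"))
        features.append(Feature(f"{pid}b", "chr1", b_start, b_end, "-", "cis_NAT",
                                partner_id=f"{pid}a"))
        sequences[f"{pid}a"] = _random_seq(rng, 400)
        sequences[f"{pid}b"] = _random_seq(rng, 400)

    for i in range(config.n_trans_nat_pairs):
        pid = f"TRA{i + 1:03d}"
        a_start, a_end = place(400)
        b_start, b_end = place(400)
        features.append(Feature(f"{pid}a", "chr1", a_start, a_end, "+", "trans_NAT",
                                partner_id=f"{pid}b"))
        features.append(Feature(f"{pid}b", "chr1", b_start, b_end, "+", "trans_NAT",
                                partner_id=f"{pid}a"))
        sequences[f"{pid}a"] = _random_seq(rng, 400)
        sequences[f"{pid}b"] = _random_seq(rng, 400)

    for i in range(config.n_lncrna):
        lid = f"LNC{i + 1:03d}"
        start, end = place(300)
        features.append(Feature(lid, "chr1", start, end, "+", "lncRNA"))
        sequences[lid] = _random_seq(rng, 300)

    catalog = LocusCatalog(features=features)
    catalog.planted_sites = planted_sites  # type: ignore[attr-defined]
    return catalog, sequences


def _mutate_outside_seed(site: str, mirna_len: int, n_mm: int,
                         rng: np.random.Generator) -> str:
    """Introduce mismatches at site positions pairing with non-seed miRNA
    positions (outside 2-13 from the miRNA 5' end) so planted hits stay
    under the stringent expectation cutoff."""
    if n_mm == 0:
        return site
    # miRNA position p (1-based) pairs with site index len-p
    candidates = [mirna_len - p for p in range(14, mirna_len + 1)]
    chosen = rng.choice(candidates, size=min(n_mm, len(candidates)), replace=False)
    out = list(site)
    for idx in chosen:
        current = out[idx]
        options = [b for b in "ACGT" if b != current]
        out[idx] = options[int(rng.integers(0, 3))]
    return "".join(out)


def sirna_clusters(catalog: LocusCatalog) -> pd.DataFrame:
    """Cluster intervals for every sRNA-producing locus (deterministic).

    miRNA loci produce one cluster covering the locus; each cis-NAT pair
    one cluster over the transcript overlap; each trans-NAT pair one
    cluster inside transcript A; each lncRNA one internal cluster.
    """
    rows = []
    for f in catalog.by_class("miRNA"):
        rows.append({"cluster": f.id, "chrom": f.chrom, "start": f.start,
                     "end": f.end, "strand": f.strand})
    for a, b in catalog.nat_pairs("cis"):
        pid = a.id[:-1]
        start, end = max(a.start, b.start), min(a.end, b.end)
        rows.append({"cluster": f"{pid}_sirna", "chrom": a.chrom, "start": start,
                     "end": end, "strand": "."})
    for a, _b in catalog.nat_pairs("trans"):
        pid = a.id[:-1]
        rows.append({"cluster": f"{pid}_sirna", "chrom": a.chrom,
                     "start": a.start + 100, "end": a.start + 200, "strand": "."})
    for f in catalog.by_class("lncRNA"):
        rows.append({"cluster": f"{f.id}_sirna", "chrom": f.chrom,
                     "start": f.start + 50, "end": f.start + 150, "strand": "."})
    return pd.DataFrame(rows)


def simulate_counts(
    catalog: LocusCatalog, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw NB counts for the sRNA and mRNA layers and return the truth.

    sRNA rows are miRNAs plus nat-siRNA/lncRNA-derived clusters; mRNA rows
    are every transcript-level feature (targets, TFs, NAT transcripts,
    lncRNAs).
    """
    rng = config._rng(1)
    design = config.samples()
    truth = SyntheticTruth()

    clusters = sirna_clusters(catalog)
    srna_ids = list(clusters["cluster"])
    mrna_ids = [f.id for f in catalog
                if f.rna_class in ("other", "cis_NAT", "trans_NAT", "lncRNA")]

    # planted log2FC per (feature, time point); cold samples only
    effects: dict[tuple[str, str], float] = {}

    def plant(fid: str, tp: str, lfc: float) -> None:
        effects[(fid, tp)] = effects.get((fid, tp), 0.0) + lfc
        truth.de_features.add((fid, tp, lfc))

    # classical nat-siRNA regulons on half of the cis pairs (none in a null study)
    cis_pairs = catalog.nat_pairs("cis")
    n_regulons = (len(cis_pairs) + 1) // 2 if config.de_fraction > 0 else 0
    for a, b in cis_pairs[:n_regulons]:
        pid = a.id[:-1]
        tp = TIME_POINTS[int(rng.integers(0, len(TIME_POINTS)))]
        plant(a.id, tp, config.de_log2fc)           # driver transcript up
        plant(b.id, tp, -config.de_log2fc)          # partner transcript down
        plant(f"{pid}_sirna", tp, config.de_log2fc)  # siRNA cluster up
        truth.planted_regulons.add((pid, a.id, b.id, tp))

    # DE miRNAs with coupled target anticorrelation
    mirna_feats = catalog.by_class("miRNA")
    n_de_mirna = (max(1, round(config.de_fraction * len(mirna_feats)))
                  if config.de_fraction > 0 else 0)
    de_mirna_idx = rng.choice(len(mirna_feats), size=n_de_mirna, replace=False)
    planted_sites = getattr(catalog, "planted_sites", {})
    target_of = {mid: gid for gid, (mid, _off) in planted_sites.items()}
    for idx in sorted(de_mirna_idx):
        mid = mirna_feats[idx].id
        tp = TIME_POINTS[int(rng.integers(0, len(TIME_POINTS)))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        beta = sign * config.de_log2fc
        plant(mid, tp, beta)
        gid = target_of.get(mid)
        if gid is not None and config.coupling_strength > 0:
            tgt_beta = -config.coupling_strength * beta
            plant(gid, tp, tgt_beta)
            category = "inverse" if abs(tgt_beta) >= 1 else "partner_unchanged"
            truth.planted_target_pairs.add((mid, gid, category))
        elif gid is not None:
            truth.planted_target_pairs.add((mid, gid, "partner_unchanged"))

    # independent DE on remaining sRNA clusters and mRNAs
    planted_ids = {fid for fid, _tp in effects}
    for pool in (srna_ids, mrna_ids):
        free = [fid for fid in pool if fid not in planted_ids]
        n_extra = round(config.de_fraction * len(free))
        if n_extra:
            chosen = rng.choice(len(free), size=n_extra, replace=False)
            for k in sorted(chosen):
                tp = TIME_POINTS[int(rng.integers(0, len(TIME_POINTS)))]
                sign = 1.0 if rng.random() < 0.5 else -1.0
                plant(free[k], tp, sign * config.de_log2fc)

    # planted effects sit on detectably expressed loci: a regulon or
    # coupled pair planted on a feature below the detection bin would be
    # invisible by construction
    floored = {fid for fid, _tp in effects}
    srna = _draw_counts(srna_ids, design, effects, config, rng, floored=floored)
    mrna = _draw_counts(mrna_ids, design, effects, config, rng, floored=floored)
    return srna, mrna, truth


def draw_nb_counts(
    feature_ids: list[str],
    design: pd.DataFrame,
    config: SimulationConfig,
    effects: Optional[dict[tuple[str, str], float]] = None,
    base_means: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """NB count matrix under the generator's model for arbitrary features.

    ``effects`` maps (feature id, time point) -> log2FC applied in cold
    samples; ``base_means`` fixes per-feature means q_i instead of the
    default log-normal draw (scalars broadcast).
    """
    if rng is None:
        rng = config._rng(4)
    return _draw_counts(feature_ids, design, effects or {}, config, rng,
                        base_means=base_means)


def _draw_counts(feature_ids: list[str], design: pd.DataFrame,
                 effects: dict[tuple[str, str], float], config: SimulationConfig,
                 rng: np.random.Generator,
                 base_means: Optional[np.ndarray] = None,
                 floored: Optional[set[str]] = None) -> pd.DataFrame:
    n_feat, n_samp = len(feature_ids), len(design)
    if base_means is not None:
        q = np.broadcast_to(np.asarray(base_means, dtype=float), (n_feat,)).copy()
    else:
        q = rng.lognormal(mean=np.log(50.0), sigma=1.5, size=n_feat)
        q *= config.library_size_mean / q.sum()
    if floored:
        mask = np.asarray([fid in floored for fid in feature_ids])
        q[mask] = np.maximum(q[mask], 100.0)
    if config.nb_dispersion is None:
        alpha = np.exp(rng.uniform(np.log(0.01), np.log(0.5), size=n_feat))
    else:
        alpha = np.full(n_feat, float(config.nb_dispersion))
    s = rng.lognormal(mean=0.0, sigma=0.15, size=n_samp)

    lfc = np.zeros((n_feat, n_samp))
    cold = (design["condition"] == "cold").to_numpy()
    for i, fid in enumerate(feature_ids):
        for j in range(n_samp):
            if cold[j]:
                lfc[i, j] = effects.get((fid, design["time"].iloc[j]), 0.0)
    mean = q[:, None] * s[None, :] * np.exp2(lfc)
    counts = _nb_draw(mean, alpha[:, None], rng)
    return pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature"),
                        columns=list(design["sample"]))


def _nb_draw(mean: np.ndarray, alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """NB(mu, Var = mu + alpha mu^2) via numpy's (n, p) parameterization."""
    alpha = np.broadcast_to(alpha, mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / alpha[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


# ---------------------------------------------------------------------------
# Regulatory edge tables and regulator-driven expression


def generate_edge_tables(catalog: LocusCatalog, config: SimulationConfig) -> pd.DataFrame:
    """Tiered regulatory edges plus miRNA_predicted edges for planted pairs.

    Each target gene gets one TF regulator assigned round-robin, so with
    n_tf >= n_targets every regulator is private to its target: held-out
    target genes in the predictive-power cross-validation are then
    genuinely unseen, and any generalization must flow through the shared
    familywise weights rather than through memorized regulator rows.
    """
    rng = config._rng(3)
    tf_ids = sorted(f.id for f in catalog if f.id.startswith("TF"))
    gene_ids = sorted(f.id for f in catalog if f.id.startswith("GENE"))
    sources = ("validated", "CE", "FunTFBS")
    rows = []
    for i, gene in enumerate(gene_ids):
        rows.append({
            "regulator": tf_ids[i % len(tf_ids)],
            "target": gene,
            "source": sources[int(rng.integers(0, 3))],
            "binding_site_count": int(rng.integers(1, 4)),
        })
    planted_sites = getattr(catalog, "planted_sites", {})
    for gid, (mid, _off) in sorted(planted_sites.items()):
        rows.append({"regulator": mid, "target": gid, "source": "miRNA_predicted",
                     "binding_site_count": 1})
    return pd.DataFrame(rows)


def simulate_regulated_expression(
    network,
    config: SimulationConfig,
    ceiling_r: Optional[float] = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Log-scale expression where targets are additive functions of their
    regulators' familywise-aggregated expression plus Gaussian noise.

    Each regulator family carries one signed weight shared by all its
    edges; a target's log expression is the weighted sum over the families
    regulating it of the family's aggregated (summed) regulator
    expression, restricted to the target's own regulators.  When
    ``ceiling_r`` is given, the per-target noise SD is set so the analytic
    Pearson ceiling sqrt(Var_sig / (Var_sig + sigma^2)) equals it exactly;
    otherwise ``config.edge_noise_sd`` applies to every target.

    Targets without any regulator in the network are excluded and logged.
    """
    from .grn import regulators_of  # local import to avoid a cycle

    rng = config._rng(2)
    design = config.samples()
    samples = list(design["sample"])
    n_samp = len(samples)
    truth = SyntheticTruth(noise_sd=(config.edge_noise_sd if ceiling_r is None else None))

    reg_map = regulators_of(network)
    regulators = sorted({r for regs in reg_map.values() for r, _src in regs})
    targets = sorted(reg_map)
    dropped = [t for t in targets if not reg_map[t]]
    for t in dropped:
        logger.warning("target %s has no regulator; excluded from expression simulation", t)
    targets = [t for t in targets if reg_map[t] and t not in set(regulators)]

    # regulator log-expression: mild per-time-point level + dominant
    # replicate scatter, so no target is predictable from the time point alone
    tp_index = design["time"].map({tp: k for k, tp in enumerate(TIME_POINTS)}).to_numpy()
    reg_expr = np.empty((len(regulators), n_samp))
    for i in range(len(regulators)):
        tp_level = rng.normal(5.0, 0.3, size=len(TIME_POINTS))
        reg_expr[i] = tp_level[tp_index] + rng.normal(0.0, 1.0, size=n_samp)
    reg_expr_df = pd.DataFrame(reg_expr, index=regulators, columns=samples)

    families = {n: (network.nodes[n].get("family") or n) for n in regulators}
    fam_weight: dict[str, float] = {}
    for fam in sorted(set(families.values())):
        w = float(rng.uniform(0.5, 1.5))
        if rng.random() < 0.5:
            w = -w
        fam_weight[fam] = w

    rows = np.empty((len(targets), n_samp))
    sigmas = np.empty(len(targets))
    for gi, g in enumerate(targets):
        signal = np.zeros(n_samp)
        for reg, _src in sorted(reg_map[g]):
            fam = families[reg]
            w = fam_weight[fam]
            signal += w * reg_expr_df.loc[reg].to_numpy()
            truth.functional_edges.add((reg, g, w))
        if ceiling_r is not None:
            sd_sig = float(np.std(signal))
            sigma = sd_sig * np.sqrt(max(1.0 / ceiling_r**2 - 1.0, 0.0))
        else:
            sigma = config.edge_noise_sd
        sigmas[gi] = sigma
        rows[gi] = signal + rng.normal(0.0, 1.0, size=n_samp) * sigma
    if ceiling_r is not None and len(sigmas):
        truth.noise_sd = float(np.mean(sigmas))

    expr = pd.concat(
        [reg_expr_df,
         pd.DataFrame(rows, index=targets, columns=samples)]
    )
    expr.index.name = "feature"
    return expr, truth
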