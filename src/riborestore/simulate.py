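"""Synthetic study generator with planted compensation structure.

Emulates the study design the pipeline targets: a panel of cell lines
(13 by default) profiled at the genomic level (probe log-ratio tracks with
recurrent segmental gains/losses), at the transcriptome level (gene dosage
drives transcription linearly in copy state) and at the translatome level,
where planted RESTORE genes carry a translational-efficiency component that
opposes their dosage change and ENHANCE genes one that magnifies it.  A set
of histone-like families receives dispersed transcription but per-line
translatome rescaling towards a fixed stoichiometric target, with one
compensation-disabled control line.  A survival cohort, a protein-complex
catalog, a pan-cancer alteration-frequency table and category tables round
out the inputs, so that every downstream stage is testable with no
external data.

The generative model, per gene g and line i with integer copy state
cn(g, i) (loss -1, neutral 0, gain +1, amplification +2):

    TC(g,i) = mu_g + beta * cn(g,i) + eps,            eps ~ N(0, sigma)
    TL(g,i) = TC(g,i) + delta(g,i) + eps',            eps' ~ N(0, sigma)

    delta = -gamma * beta * cn   for RESTORE genes (compensation)
          = +gamma * beta * cn   for ENHANCE genes (magnification)
          = 0                    otherwise

gamma in [0, 1] is the compensation fraction: gamma = 1 restores the
baseline exactly in the zero-noise limit.  All generators are bitwise
reproducible given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from riborestore import io as rio

CLASSES = ("RESTORE_UP", "RESTORE_DOWN", "ENHANCE_UP", "ENHANCE_DOWN")

# segment-mean log2 ratios per copy state offset
STATE_MEANS = {-1: -1.0, 0: 0.0, 1: 0.58, 2: 2.0}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic panel."""

    seed: int = 7
    n_genes: int = 2000
    n_chrom: int = 10
    n_lines: int = 13
    gene_length: int = 10_000
    gene_spacing: int = 10_000

    # planted compensation classes
    n_restore_up: int = 60
    n_restore_down: int = 60
    n_enhance_up: int = 40
    n_enhance_down: int = 40

    # recurrent CNA structure
    recurrent_region_count: int = 12
    region_width_genes: int = 20
    n_amp_regions: int = 1
    min_lines_per_region: int = 8
    sigma_probe: float = 0.1

    # expression model
    dosage_effect: float = 1.0     # beta, log2 per copy-state step
    compensation: float = 1.0      # gamma in [0, 1]
    noise_sd: float = 0.25         # sigma, log2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5

    # histone-like stoichiometric families (member counts per family)
    histone_families: dict = field(
        default_factory=lambda: {"H1": 3, "H2A": 12, "H2B": 16, "H3": 5, "H4": 9}
    )
    histone_tc_spread: float = 1.0   # +/- log2 per-line family imbalance
    stoich_noise_sd: float = 0.05
    control_line_index: int = 4      # compensation-disabled line (KELLY-like)

    # category proportions
    frac_rbp: float = 0.08
    frac_mirna: float = 0.03
    frac_tf: float = 0.05
    frac_kinase: float = 0.04
    n_saturated_decoys: int = 5
    n_dim_decoys: int = 20

    # survival cohort
    cohort_size: int = 200
    baseline_hazard: float = 0.1
    prognostic_effect: float = 1.2   # log hazard ratio of the adverse group
    censoring_rate: float = 0.2
    prognostic_fraction: float = 0.7

    # catalogs
    n_complexes: int = 60
    complex_size_min: int = 2
    complex_size_max: int = 10
    complex_diffrep_bias: float = 0.5
    n_tumor_types: int = 10
    pan_cancer_concordance: float = 0.9

    def validate(self) -> None:
        n_planted = (self.n_restore_up + self.n_restore_down
                     + self.n_enhance_up + self.n_enhance_down)
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted class counts ({n_planted}) exceed n_genes ({self.n_genes})"
            )
        if not 0.0 <= self.compensation <= 1.0:
            raise ValueError("compensation fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.sigma_probe < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.complex_size_min < 2:
            raise ValueError("complexes must have at least 2 members")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")

    def line_names(self) -> list[str]:
        return [f"line{i + 1:02d}" for i in range(self.n_lines)]

    @property
    def control_line(self) -> str:
        return self.line_names()[self.control_line_index]


@dataclass
class GroundTruth:
    """Planted structure, serialised alongside the emitted data."""

    gene_class: dict            # gene_id -> class label
    copy_state: pd.DataFrame    # genes x lines integer copy-state offsets
    family_targets: dict        # family -> target linear-scale sum
    control_line: str
    prognostic_genes: list = field(default_factory=list)
    regions: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        payload = {
            "gene_class": self.gene_class,
            "copy_state": {
                "genes": list(self.copy_state.index),
                "lines": list(self.copy_state.columns),
                "values": self.copy_state.to_numpy().astype(int).tolist(),
            },
            "family_targets": self.family_targets,
            "control_line": self.control_line,
            "prognostic_genes": self.prognostic_genes,
            "regions": self.regions,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        cs = pd.DataFrame(np.asarray(d["copy_state"]["values"], dtype=int),
                          index=d["copy_state"]["genes"],
                          columns=d["copy_state"]["lines"])
        return cls(gene_class=d["gene_class"], copy_state=cs,
                   family_targets=d["family_targets"],
                   control_line=d["control_line"],
                   prognostic_genes=d["prognostic_genes"],
                   regions=d["regions"])


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Tile non-overlapping gene loci over chromosomes and tag categories.

    Histone-family members are placed at the end of the last chromosome so
    recurrent CNA regions (drawn on earlier genes) never cover them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    per_chrom = int(np.ceil(n / config.n_chrom))
    genes: list[rio.GeneAnnotation] = []
    for idx in range(n):
        chrom = f"chr{idx // per_chrom + 1}"
        offset = idx % per_chrom
        start = offset * (config.gene_length + config.gene_spacing)
        genes.append(
            rio.GeneAnnotation(
                gene_id=f"g{idx + 1:05d}", symbol=f"G{idx + 1}", chrom=chrom,
                start=start, end=start + config.gene_length, strand="+",
            )
        )
    catalog = rio.annotation_to_frame(genes)

    fam_sizes = list(config.histone_families.items())
    n_hist = sum(s for _, s in fam_sizes)
    if n_hist > n:
        raise ValueError("histone family members exceed n_genes")
    fam_col = [None] * n
    pos = n - n_hist
    for fam, size in fam_sizes:
        for _ in range(size):
            fam_col[pos] = fam
            pos += 1
    catalog["family"] = fam_col

    non_hist = np.array([f is None for f in fam_col])
    cats = [set() for _ in range(n)]
    for tag, frac in (("RBP", config.frac_rbp), ("miRNA", config.frac_mirna),
                      ("TF", config.frac_tf), ("kinase", config.frac_kinase)):
        k = int(round(frac * n))
        chosen = rng.choice(np.flatnonzero(non_hist), size=k, replace=False)
        for j in chosen:
            cats[j].add(tag)
    for j in np.flatnonzero(~non_hist):
        cats[j].add("histone")
    catalog["categories"] = [frozenset(c) for c in cats]
    return catalog


def simulate_cna(
    catalog: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict, list[dict]]:
    """Plant recurrent segmental CNAs and place compensation classes.

    Returns (probe_tracks, copy_state, gene_class, regions).  Probe
    log-ratios are segment mean + N(0, sigma_probe), one probe per gene at
    its midpoint.  RESTORE_UP / ENHANCE_DOWN genes live in loss regions,
    RESTORE_DOWN / ENHANCE_UP in gain (or amplification) regions; each
    region is altered with a shared direction in at least
    ``min_lines_per_region`` lines.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    lines = config.line_names()
    gene_ids = list(catalog.index)
    n = len(gene_ids)
    hist_mask = catalog["family"].notna().to_numpy()

    width = config.region_width_genes
    n_regions = config.recurrent_region_count
    if n_regions % 2:
        n_regions += 1  # equal numbers of loss and gain regions
    # candidate region starts on non-histone genes, non-overlapping
    eligible = np.flatnonzero(~hist_mask)
    max_start = eligible.max() - width
    starts: list[int] = []
    attempts = 0
    while len(starts) < n_regions:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("region widths exceed available chromosome length")
        s = int(rng.integers(0, max_start))
        if hist_mask[s:s + width].any():
            continue
        if all(abs(s - t) >= width + 5 for t in starts):
            starts.append(s)
    starts.sort()
    directions = np.array([-1, 1] * (n_regions // 2))
    rng.shuffle(directions)
    amp_flags = np.zeros(n_regions, dtype=bool)
    gain_idx = np.flatnonzero(directions == 1)
    amp_flags[gain_idx[: config.n_amp_regions]] = True

    copy_state = pd.DataFrame(0, index=gene_ids, columns=lines, dtype=int)
    regions: list[dict] = []
    for s, d, amp in zip(starts, directions, amp_flags):
        n_aff = int(rng.integers(config.min_lines_per_region, config.n_lines + 1))
        affected = sorted(rng.choice(config.n_lines, size=n_aff, replace=False).tolist())
        state = 2 if (d == 1 and amp) else int(d)
        rows = slice(s, s + width)
        for li in affected:
            copy_state.iloc[rows, li] = state
        regions.append({
            "start_gene": gene_ids[s], "end_gene": gene_ids[s + width - 1],
            "direction": "loss" if d == -1 else ("amplification" if amp else "gain"),
            "state": state, "lines": [lines[li] for li in affected],
        })

    # place planted classes inside appropriately-signed regions
    loss_pool: list[int] = []
    gain_pool: list[int] = []
    for s, d in zip(starts, directions):
        pool = loss_pool if d == -1 else gain_pool
        pool.extend(range(s, s + width))
    rng.shuffle(loss_pool)
    rng.shuffle(gain_pool)
    need_loss = config.n_restore_up + config.n_enhance_down
    need_gain = config.n_restore_down + config.n_enhance_up
    if need_loss > len(loss_pool) or need_gain > len(gain_pool):
        raise ValueError(
            "not enough region genes to host planted classes; increase "
            "recurrent_region_count or region_width_genes"
        )
    gene_class: dict[str, str] = {}
    for j in loss_pool[: config.n_restore_up]:
        gene_class[gene_ids[j]] = "RESTORE_UP"
    for j in loss_pool[config.n_restore_up: need_loss]:
        gene_class[gene_ids[j]] = "ENHANCE_DOWN"
    for j in gain_pool[: config.n_restore_down]:
        gene_class[gene_ids[j]] = "RESTORE_DOWN"
    for j in gain_pool[config.n_restore_down: need_gain]:
        gene_class[gene_ids[j]] = "ENHANCE_UP"

    # probe tracks: one probe per gene midpoint
    mid = ((catalog["start"] + catalog["end"]) // 2).to_numpy()
    seg_mean = np.vectorize(STATE_MEANS.get)(copy_state.to_numpy())
    noise = rng.normal(0.0, config.sigma_probe, size=(n, config.n_lines)) \
        if config.sigma_probe > 0 else np.zeros((n, config.n_lines))
    values = seg_mean + noise
    tracks = pd.DataFrame({
        "chrom": np.repeat(catalog["chrom"].to_numpy(), config.n_lines),
        "position": np.repeat(mid, config.n_lines),
        "sample": np.tile(lines, n),
        "log_ratio": values.ravel(),
    })
    return tracks, copy_state, gene_class, regions


def simulate_expression(
    catalog: pd.DataFrame,
    copy_state: pd.DataFrame,
    gene_class: dict,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict, GroundTruth]:
    """Paired transcriptome (TC) / translatome (TL) matrices plus QC flags.

    Implements the dosage + compensation model from the module docstring.
    Histone-family members get per-line dispersed TC (family-level log2
    shifts spanning +/- ``histone_tc_spread``) while TL is rescaled per line
    so each family's linear-scale sum matches its stoichiometric target,
    except in the control line where the rescaling is disabled.
    """
    config.validate()
    if not copy_state.index.equals(catalog.index):
        raise ValueError("copy_state must cover every annotated gene")
    rng = np.random.default_rng(config.seed + 2)
    lines = list(copy_state.columns)
    gene_ids = list(catalog.index)
    n, m = len(gene_ids), len(lines)
    beta, gamma, sigma = config.dosage_effect, config.compensation, config.noise_sd

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    # planted compensation genes and histone members are expressed genes by
    # definition (the phenomenon is scored over detectable loci; histones
    # are abundantly transcribed), so their baselines are drawn from the
    # expressed upper part of the baseline distribution.
    planted_idx = np.array(
        [j for j, g in enumerate(gene_ids)
         if g in gene_class or pd.notna(catalog["family"].iloc[j])],
        dtype=int)
    if len(planted_idx):
        u = rng.uniform(0.35, 1.0, size=len(planted_idx))
        mu[planted_idx] = (config.baseline_mean
                           + config.baseline_sd * stats.norm.ppf(u))
    cn = copy_state.to_numpy(dtype=float)
    eps1 = rng.normal(0.0, sigma, size=(n, m)) if sigma > 0 else np.zeros((n, m))
    eps2 = rng.normal(0.0, sigma, size=(n, m)) if sigma > 0 else np.zeros((n, m))
    tc = mu[:, None] + beta * cn + eps1

    sign = np.zeros(n)
    for j, g in enumerate(gene_ids):
        cls = gene_class.get(g)
        if cls in ("RESTORE_UP", "RESTORE_DOWN"):
            sign[j] = -1.0
        elif cls in ("ENHANCE_UP", "ENHANCE_DOWN"):
            sign[j] = 1.0
    delta = sign[:, None] * gamma * beta * cn
    tl = tc + delta + eps2

    # histone families: dispersed TC, stoichiometric TL.  The shared target
    # encodes nucleosome equimolarity: every family is rescaled to the same
    # linear-scale sum, the way histone types are needed in fixed ratio.
    fam = catalog["family"]
    family_targets: dict[str, float] = {}
    s_noise = config.stoich_noise_sd
    ctrl = config.control_line
    fam_labels = [f for f in fam.dropna().unique()]
    base_sums = {
        f: float(np.sum(2.0 ** mu[np.flatnonzero((fam == f).to_numpy())]))
        for f in fam_labels
    }
    common_target = float(np.exp(np.mean(np.log(list(base_sums.values()))))) \
        if base_sums else 0.0
    for family in fam_labels:
        members = np.flatnonzero((fam == family).to_numpy())
        shifts = np.linspace(-config.histone_tc_spread, config.histone_tc_spread, m)
        shifts = rng.permutation(shifts)
        base_tc = (mu[members, None]
                   + rng.normal(0.0, sigma, size=(len(members), m))
                   if sigma > 0 else np.repeat(mu[members, None], m, axis=1))
        tc[members, :] = base_tc + shifts[None, :]
        target = common_target
        family_targets[family] = target
        lin_sum = np.sum(2.0 ** tc[members, :], axis=0)
        rescale = np.log2(target / lin_sum)
        tl_noise = (rng.normal(0.0, s_noise, size=(len(members), m))
                    if s_noise > 0 else np.zeros((len(members), m)))
        tl[members, :] = tc[members, :] + rescale[None, :] + tl_noise
        ci = lines.index(ctrl)
        tl[members, ci] = tc[members, ci] + tl_noise[:, ci]

    tc_df = pd.DataFrame(tc, index=gene_ids, columns=lines)
    tl_df = pd.DataFrame(tl, index=gene_ids, columns=lines)

    # QC flags: a few decoy background genes fail filtering rules
    shape = (n, m)
    flags = {
        "above_background": pd.DataFrame(np.ones(shape, bool), index=gene_ids, columns=lines),
        "good_spot": pd.DataFrame(np.ones(shape, bool), index=gene_ids, columns=lines),
        "saturated": pd.DataFrame(np.zeros(shape, bool), index=gene_ids, columns=lines),
        "outlier": pd.DataFrame(np.zeros(shape, bool), index=gene_ids, columns=lines),
    }
    protected = set(gene_class) | set(catalog.index[fam.notna()])
    background = [g for g in gene_ids if g not in protected]
    decoys = rng.choice(background,
                        size=config.n_saturated_decoys + config.n_dim_decoys,
                        replace=False)
    for g in decoys[: config.n_saturated_decoys]:
        flags["saturated"].loc[g, lines[int(rng.integers(m))]] = True
    for g in decoys[config.n_saturated_decoys:]:
        flags["above_background"].loc[g, :] = False

    truth = GroundTruth(gene_class=dict(gene_class), copy_state=copy_state,
                        family_targets=family_targets, control_line=ctrl)
    return tc_df, tl_df, flags, truth


def simulate_cohort(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, list[str]]:
    """Survival cohort with planted prognostic RESTORE genes.

    A latent binary risk group multiplies the exponential baseline hazard by
    exp(prognostic_effect).  Planted prognostic genes express their risk
    group in the adverse direction of their class: RESTORE_DOWN genes are
    high in high-risk patients, RESTORE_UP genes low.  Censoring is
    independent: a patient is censored with probability ``censoring_rate``
    at a uniform fraction of their event time.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    n = config.cohort_size
    risk = rng.integers(0, 2, size=n)
    hazard = config.baseline_hazard * np.exp(config.prognostic_effect * risk)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < config.censoring_rate
    u = rng.random(n)
    time = np.where(censored, u * t_event, t_event)
    event = (~censored).astype(int)

    restore_genes = sorted(g for g, c in truth.gene_class.items()
                           if c.startswith("RESTORE"))
    n_prog = int(round(config.prognostic_fraction * len(restore_genes)))
    prognostic = sorted(rng.choice(restore_genes, size=n_prog, replace=False).tolist())
    expr = {}
    for g in restore_genes:
        noise = rng.normal(0.0, 1.0, size=n)
        if g in prognostic:
            direction = 1.0 if truth.gene_class[g] == "RESTORE_DOWN" else -1.0
            expr[g] = 8.0 + 2.0 * direction * risk + noise
        else:
            expr[g] = 8.0 + noise
    cohort = pd.DataFrame({"time": time, "event": event, **expr},
                          index=pd.Index([f"pt{i + 1:04d}" for i in range(n)],
                                         name="patient_id"))
    truth.prognostic_genes = prognostic
    return cohort, prognostic


def simulate_catalogs(
    catalog: pd.DataFrame, truth: GroundTruth, config: SimulationConfig
) -> tuple[dict[str, set[str]], pd.DataFrame, dict[str, set[str]]]:
    """Complex catalog, pan-cancer frequency table and category tables.

    The frequency table gives per-gene gain and loss frequencies across
    tumor types; the concordant alteration (gain for RESTORE_DOWN, loss for
    RESTORE_UP) of planted RESTORE genes is raised towards 1 by the planted
    concordance c:  f = (1 - c) * background + c * 1.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 4)
    gene_ids = list(catalog.index)

    planted = sorted(truth.gene_class)
    hist = list(catalog.index[catalog["family"].notna()])
    biased_pool = planted + hist
    complexes: dict[str, set[str]] = {}
    for k in range(config.n_complexes):
        size = int(rng.integers(config.complex_size_min, config.complex_size_max + 1))
        n_biased = int(round(config.complex_diffrep_bias * size))
        members = set(rng.choice(biased_pool, size=min(n_biased, len(biased_pool)),
                                 replace=False).tolist())
        while len(members) < size:
            members.add(str(rng.choice(gene_ids)))
        complexes[f"cplx{k + 1:03d}"] = members

    types = [f"tumor{t + 1:02d}" for t in range(config.n_tumor_types)]
    c = config.pan_cancer_concordance
    gain = rng.uniform(0.05, 0.30, size=(len(gene_ids), len(types)))
    loss = rng.uniform(0.05, 0.30, size=(len(gene_ids), len(types)))
    idx = {g: j for j, g in enumerate(gene_ids)}
    for g, cls in truth.gene_class.items():
        j = idx[g]
        if cls == "RESTORE_DOWN":
            gain[j, :] = (1 - c) * gain[j, :] + c
        elif cls == "RESTORE_UP":
            loss[j, :] = (1 - c) * loss[j, :] + c
    freq = pd.DataFrame(
        np.hstack([gain, loss]), index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"{t}:gain" for t in types] + [f"{t}:loss" for t in types],
    )

    categories: dict[str, set[str]] = {}
    for tag in ("RBP", "miRNA", "TF", "kinase", "histone"):
        members = {g for g, row in catalog.iterrows() if tag in row["categories"]}
        if members:
            categories[tag] = members
    return complexes, freq, categories


@dataclass
class SyntheticDataset:
    """Everything one simulated study emits, in memory."""

    config: SimulationConfig
    annotation: pd.DataFrame
    probe_tracks: pd.DataFrame
    copy_state: pd.DataFrame
    transcriptome: pd.DataFrame
    translatome: pd.DataFrame
    qc_flags: dict
    truth: GroundTruth
    cohort: pd.DataFrame
    complexes: dict
    pan_cancer: pd.DataFrame
    categories: dict


def simulate_all(config: SimulationConfig, outdir: str | Path | None = None) -> SyntheticDataset:
    """Run every generator and, optionally, write all files core_io reads."""
    catalog = simulate_annotation(config)
    tracks, copy_state, gene_class, regions = simulate_cna(catalog, config)
    tc, tl, flags, truth = simulate_expression(catalog, copy_state, gene_class, config)
    truth.regions = regions
    cohort, _ = simulate_cohort(truth, config)
    complexes, freq, categories = simulate_catalogs(catalog, truth, config)
    ds = SyntheticDataset(config=config, annotation=catalog, probe_tracks=tracks,
                          copy_state=copy_state, transcriptome=tc, translatome=tl,
                          qc_flags=flags, truth=truth, cohort=cohort,
                          complexes=complexes, pan_cancer=freq, categories=categories)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rio.write_annotation(catalog, outdir / "annotation.bed")
        rio.write_probe_tracks(tracks, outdir / "probes.tsv")
        rio.write_expression_matrix(tc, outdir / "transcriptome.tsv")
        rio.write_expression_matrix(tl, outdir / "translatome.tsv")
        cohort.to_csv(outdir / "cohort.tsv", sep="\t")
        freq.to_csv(outdir / "pan_cancer_freq.tsv", sep="\t")
        pd.DataFrame(
            [(cid, g) for cid, mem in complexes.items() for g in sorted(mem)],
            columns=["complex_id", "gene_id"],
        ).to_csv(outdir / "complexes.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(c, g) for c, mem in categories.items() for g in sorted(mem)],
            columns=["category", "gene_id"],
        ).to_csv(outdir / "categories.tsv", sep="\t", index=False)
        fam = catalog["family"].dropna()
        pd.DataFrame({"gene_id": fam.index, "family": fam.to_numpy()}).to_csv(
            outdir / "families.tsv", sep="\t", index=False)
        truth.save(outdir / "ground_truth.json")
        cfg = asdict(config)
        (outdir / "sim_config.json").write_text(json.dumps(cfg, indent=1))
    return ds
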