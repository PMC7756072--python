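"""Synthetic inputs with planted ground truth.

Two designs are emulated.  (1) A cryoinjury time course: injured,
sham-operated and healthy fish sampled on a 10-timepoint grid
(1, 4, 7, 14, 21, 30, 45, 60, 120, 160 days post injury), where a
fraction of genes follows one of five archetype log2FC trajectories;
sham fish carry a damped copy of the injury response that is forced to
zero by 30 dpi.  (2) A paired tumor-normal cohort with per-patient
baseline effects, planted differentially expressed genes, planted
gene-set signal, and repressive miRNAs whose predicted targets are
pushed down in proportion to the miRNA's per-sample activity.

Counts are negative binomial with variance mu + phi mu^2; the per-gene
dispersion follows a log-linear trend in the mean plus lognormal
scatter, and library sizes are lognormal (sd 0.3) so TMM normalization
has real work to do.  Everything derives from one integer seed through
named substreams: the same config reproduces identical outputs bit for
bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .enrichment import GeneSetCollection
from .ortho import OrthologMap

#: the injury time-course sampling grid, in days post injury
DEFAULT_TIMEPOINTS = (1, 4, 7, 14, 21, 30, 45, 60, 120, 160)


def _bump(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """Unit-height Gaussian bump in log-time."""
    return np.exp(-((np.log(t) - np.log(t0)) ** 2) / (2 * width**2))


# Five archetype trajectory shapes (unit amplitude, log2FC vs days):
# 1 down with trough 4-14 dpi; 2 down early then up late; 3 up early
# then down late; 4 broad up around 21 dpi; 5 sharp up at 4-7 dpi
# returning to baseline by 120 dpi.
DEFAULT_ARCHETYPES = (
    lambda t: -_bump(t, 7.0, 0.9),
    lambda t: -_bump(t, 4.0, 0.7) + 0.6 * _bump(t, 60.0, 0.8),
    lambda t: _bump(t, 4.0, 0.7) - 0.6 * _bump(t, 60.0, 0.8),
    lambda t: _bump(t, 21.0, 1.1),
    lambda t: _bump(t, 5.5, 0.55),
)

#: sign of each archetype's dominant early response (used to plant
#: direction-consistent gene sets for the time course)
ARCHETYPE_SIGNS = (-1, -1, 1, 1, 1)


@dataclass
class MirnaBlock:
    """Repressive-miRNA design: how many miRNAs repress, how many
    targets each has, how strongly (log2FC per log2 unit of miRNA
    activity) and how noisily."""

    n_repressive: int = 1
    n_decoy: int = 19
    targets_per: int = 20
    slope: float = -1.0
    noise_sd: float = 0.2
    up_lfc: float = 2.0  # tumor up-shift of repressive miRNAs
    n_decoy_predicted: int = 200


@dataclass
class GenesetBlock:
    n_sets: int = 40
    set_size: int = 40
    planted_per_direction: int = 3
    frac_planted: float = 0.8  # fraction of a planted set drawn from planted genes


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the emulated study
    design (10-timepoint grid, four healthy controls)."""

    seed: int = 0
    n_genes: int = 2000
    timepoints: tuple = DEFAULT_TIMEPOINTS
    n_injured_per_tp: int = 3
    n_sham_per_tp: int = 2
    n_healthy: int = 4
    n_pairs: int = 10
    frac_de: float = 0.25
    effect_size: float = 2.0
    sham_scale: float = 0.3
    patient_sd: float = 0.4
    base_log_mean: float = 5.0  # natural-log mean of baseline expression
    base_log_sd: float = 1.2
    lib_sd: float = 0.3
    lib_size: float = 3e6
    disp_intercept: float = 0.08  # phi at the reference mean
    disp_slope: float = -0.3  # log-linear trend of phi in mu
    disp_scatter: float = 0.3
    amp_jitter: float = 0.2
    one2many_frac: float = 0.1
    mirna_block: MirnaBlock = field(default_factory=MirnaBlock)
    geneset_block: GenesetBlock = field(default_factory=GenesetBlock)

    def __post_init__(self) -> None:
        for frac in (self.frac_de, self.one2many_frac, self.geneset_block.frac_planted):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for count in (self.n_genes, self.n_injured_per_tp, self.n_sham_per_tp,
                      self.n_healthy, self.n_pairs):
            if count <= 0:
                raise ValueError("counts must be positive")
        tps = np.asarray(self.timepoints, dtype=float)
        if len(tps) < 2 or not (np.diff(tps) > 0).all():
            raise ValueError("timepoints must be strictly increasing")


@dataclass
class SimTruth:
    """Planted ground truth for one generated dataset."""

    archetype: dict = field(default_factory=dict)  # gene -> int or None
    tumor_lfc: dict = field(default_factory=dict)  # gene -> float
    set_direction: dict = field(default_factory=dict)  # set -> up/down/None
    mirna_targets: dict = field(default_factory=dict)  # mirna -> [genes]
    mirna_slope: dict = field(default_factory=dict)
    lib_factors: dict = field(default_factory=dict)  # sample -> float

    def planted_genes(self) -> list[str]:
        return [g for g, a in self.archetype.items() if a is not None]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _rng(config: SimConfig, *stream) -> np.random.Generator:
    """Named substream derived from the global seed (process-stable)."""
    key = [config.seed] + [
        zlib.crc32(s.encode()) if isinstance(s, str) else int(s) for s in stream
    ]
    return np.random.default_rng(key)


def _nb_counts(rng, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) draws with variance mu + phi mu^2 (Poisson at phi=0)."""
    out = np.empty_like(mu)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        n = 1.0 / phi[~pois]
        p = n / (n + mu[~pois])
        out[~pois] = rng.negative_binomial(n, p)
    return out.astype(np.int64)


def _gene_baseline(config: SimConfig, rng):
    base = np.exp(rng.normal(config.base_log_mean, config.base_log_sd, config.n_genes))
    ref = np.exp(config.base_log_mean)
    log_trend = np.log(config.disp_intercept) + config.disp_slope * np.log(base / ref)
    phi = np.exp(log_trend + rng.normal(0.0, config.disp_scatter, config.n_genes))
    return base, phi


def _planted_assignment(config: SimConfig, n_archetypes: int):
    """Shared planted-gene assignment used by both designs, so the
    same genes respond in the time course and the cohort (with tumor
    direction equal to the archetype's early sign).  Drawn from its own
    substream, hence identical across both simulate_* calls."""
    rng = _rng(config, "planted")
    n_de = int(round(config.frac_de * config.n_genes))
    idx = np.sort(rng.choice(config.n_genes, size=n_de, replace=False))
    arch = rng.permutation(np.arange(n_de) % n_archetypes) if n_de else np.array([], int)
    return idx, arch


def simulate_timecourse(config: SimConfig, archetypes=DEFAULT_ARCHETYPES):
    """Generate the injured/sham/healthy count time course.

    Injured samples of planted genes follow mean * 2^(amplitude *
    archetype curve at t); sham samples carry the same response scaled
    by ``sham_scale`` and linearly damped to zero by 30 dpi; healthy
    samples are baseline.  Returns (CountMatrix, SimTruth).
    """
    if config.frac_de > 0 and not archetypes:
        raise ValueError("frac_de > 0 requires archetype curves")
    rng = _rng(config, "timecourse")
    genes = [f"drg{i:05d}" for i in range(config.n_genes)]
    base, phi = _gene_baseline(config, rng)

    de_idx, arch_of_planted = _planted_assignment(config, len(archetypes))
    n_de = len(de_idx)
    arch = np.full(config.n_genes, -1)
    if n_de:
        arch[de_idx] = arch_of_planted
    amp = config.effect_size * (
        1.0 + rng.uniform(-config.amp_jitter, config.amp_jitter, config.n_genes)
    )

    samples, conditions, tps = [], [], []
    for t in config.timepoints:
        for r in range(config.n_injured_per_tp):
            samples.append(f"inj_t{t:g}_r{r + 1}")
            conditions.append("injured")
            tps.append(float(t))
        for r in range(config.n_sham_per_tp):
            samples.append(f"sham_t{t:g}_r{r + 1}")
            conditions.append("sham")
            tps.append(float(t))
    for r in range(config.n_healthy):
        samples.append(f"healthy_r{r + 1}")
        conditions.append("healthy")
        tps.append(np.nan)

    libf = np.exp(rng.normal(0.0, config.lib_sd, len(samples)))
    counts = np.zeros((config.n_genes, len(samples)), dtype=np.int64)
    tarr = np.asarray(config.timepoints, dtype=float)
    curve_vals = np.array([f(tarr) for f in archetypes])  # archetype x timepoint
    tp_index = {float(t): i for i, t in enumerate(tarr)}
    for j, (cond, t) in enumerate(zip(conditions, tps)):
        sig = np.zeros(config.n_genes)
        if cond in ("injured", "sham") and n_de:
            col = curve_vals[:, tp_index[t]]
            planted = arch >= 0
            sig[planted] = amp[planted] * col[arch[planted]]
            if cond == "sham":
                sig *= config.sham_scale * max(0.0, 1.0 - t / 30.0)
        mu = base * libf[j] * (config.lib_size / (base.sum() * libf[j])) * 2.0**sig
        counts[:, j] = _nb_counts(rng, mu, phi)

    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        pd.DataFrame(
            {"condition": conditions, "timepoint": tps}, index=pd.Index(samples)
        ),
    )
    truth = SimTruth(
        archetype={g: (int(a) if a >= 0 else None) for g, a in zip(genes, arch)},
        lib_factors={s: float(f) for s, f in zip(samples, libf)},
    )
    return cm, truth


def simulate_paired_cohort(config: SimConfig):
    """Generate a paired tumor-normal cohort with mRNA and miRNA counts.

    Each patient contributes one tumor and one normal sample sharing a
    per-patient, per-gene baseline effect (lognormal, sd
    ``patient_sd`` log2 units).  A fraction ``frac_de`` of genes gets a
    tumor shift of +/- ``effect_size`` log2 units (half up, half down,
    excluding miRNA targets).  Each repressive miRNA is shifted up in
    tumors; its targets' means are multiplied by 2^(slope * activity +
    noise), where activity is the miRNA's per-sample log2 deviation, so
    targets are anticorrelated with their miRNA and down in tumors.

    Returns (CountMatrix mRNA, CountMatrix miRNA, SimTruth).
    """
    if config.n_pairs < 3:
        raise ValueError("need n_pairs >= 3")
    mb = config.mirna_block
    rng = _rng(config, "cohort")
    genes = [f"hsg{i:05d}" for i in range(config.n_genes)]
    base, phi = _gene_baseline(config, rng)

    n_mirnas = mb.n_repressive + mb.n_decoy
    mirnas = [f"miR-{i + 1}" for i in range(n_mirnas)]
    repressive = mirnas[: mb.n_repressive]
    if mb.n_repressive * mb.targets_per > config.n_genes:
        raise ValueError("miRNA targets exceed gene universe")
    target_pool = rng.choice(
        config.n_genes, size=mb.n_repressive * mb.targets_per, replace=False
    )
    target_set = set(target_pool.tolist())
    mirna_targets = {
        m: sorted(int(i) for i in target_pool[k * mb.targets_per:(k + 1) * mb.targets_per])
        for k, m in enumerate(repressive)
    }

    planted_idx, arch_of_planted = _planted_assignment(config, len(ARCHETYPE_SIGNS))
    tumor_lfc = np.zeros(config.n_genes)
    for i, a in zip(planted_idx, arch_of_planted):
        if int(i) in target_set:
            continue  # miRNA coupling owns these genes
        tumor_lfc[i] = ARCHETYPE_SIGNS[a] * config.effect_size
    # miRNA targets are shifted through the repression coupling: the
    # miRNA's tumor-vs-normal activity difference is up_lfc, so targets
    # move by slope * up_lfc; the truth records that effective shift.
    for i in sorted(target_set):
        tumor_lfc[i] = mb.slope * mb.up_lfc

    samples = [f"{c}_p{i + 1}" for i in range(config.n_pairs) for c in ("tumor", "normal")]
    conds = ["tumor", "normal"] * config.n_pairs
    pair_ids = [f"p{i + 1}" for i in range(config.n_pairs) for _ in range(2)]
    libf = np.exp(rng.normal(0.0, config.lib_sd, len(samples)))

    patient_effect = rng.normal(0.0, config.patient_sd, (config.n_genes, config.n_pairs))

    # miRNA expression: per-sample log2 level, tumor up-shift for
    # repressive miRNAs, patient effect, jitter; activity = deviation
    # from each miRNA's own mean level.
    mi_base = np.exp(rng.normal(config.base_log_mean, 0.8, n_mirnas))
    mi_phi = np.full(n_mirnas, 0.05)
    mi_patient = rng.normal(0.0, config.patient_sd, (n_mirnas, config.n_pairs))
    mi_jitter = rng.normal(0.0, 0.3, (n_mirnas, len(samples)))
    mi_log2 = np.zeros((n_mirnas, len(samples)))
    for j, (cond, pid) in enumerate(zip(conds, pair_ids)):
        pi = int(pid[1:]) - 1
        up = np.array([mb.up_lfc if (m in repressive and cond == "tumor") else 0.0
                       for m in mirnas])
        mi_log2[:, j] = np.log2(mi_base) + up + mi_patient[:, pi] + mi_jitter[:, j]
    activity = mi_log2 - mi_log2.mean(axis=1, keepdims=True)

    mi_libf = np.exp(rng.normal(0.0, config.lib_sd, len(samples)))
    mi_counts = np.zeros((n_mirnas, len(samples)), dtype=np.int64)
    counts = np.zeros((config.n_genes, len(samples)), dtype=np.int64)
    repress_noise = rng.normal(0.0, mb.noise_sd, (len(target_set), len(samples)))
    tgt_rows = {int(i): r for r, i in enumerate(sorted(target_set))}
    for j, (cond, pid) in enumerate(zip(conds, pair_ids)):
        pi = int(pid[1:]) - 1
        sig = patient_effect[:, pi].copy()
        if cond == "tumor":
            sig += tumor_lfc
        for k, m in enumerate(repressive):
            for gi in mirna_targets[m]:
                sig[gi] += mb.slope * activity[k, j] + repress_noise[tgt_rows[gi], j]
        mu = base * (config.lib_size / base.sum()) * libf[j] * 2.0**sig
        counts[:, j] = _nb_counts(rng, mu, phi)
        mi_mu = 2.0 ** mi_log2[:, j]
        mi_mu = mi_mu * (config.lib_size / 10 / mi_mu.sum()) * mi_libf[j]
        mi_counts[:, j] = _nb_counts(rng, mi_mu, mi_phi)

    meta = pd.DataFrame(
        {"condition": conds, "pair_id": pair_ids}, index=pd.Index(samples)
    )
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta)
    cm_mi = CountMatrix(
        pd.DataFrame(mi_counts, index=mirnas, columns=samples), meta.copy()
    )
    truth = SimTruth(
        tumor_lfc={g: float(l) for g, l in zip(genes, tumor_lfc)},
        mirna_targets={m: [genes[i] for i in idx] for m, idx in mirna_targets.items()},
        mirna_slope={m: mb.slope for m in repressive},
        lib_factors={s: float(f) for s, f in zip(samples, libf)},
    )
    return cm, cm_mi, truth


def emit_genesets(
    config: SimConfig, truth: SimTruth, genes=None
) -> GeneSetCollection:
    """Gene-set collection over the generated universe with planted
    signal: ``planted_per_direction`` sets are composed mostly
    (``frac_planted``) of planted up (resp. down) genes; one set per
    repressive miRNA holds exactly its targets; the rest are random.
    The truth's ``set_direction`` records the planted directions.
    """
    gb = config.geneset_block
    if genes is None:
        genes = sorted(set(truth.tumor_lfc) | set(truth.archetype))
    genes = list(genes)
    if gb.set_size > len(genes):
        raise ValueError("set size exceeds gene universe")
    rng = _rng(config, "genesets")
    if truth.tumor_lfc:
        up_pool = [g for g, l in truth.tumor_lfc.items() if l > 0 and g in set(genes)]
        down_pool = [g for g, l in truth.tumor_lfc.items() if l < 0 and g in set(genes)]
    else:
        gset = set(genes)
        up_pool = [g for g, a in truth.archetype.items()
                   if a is not None and ARCHETYPE_SIGNS[a] > 0 and g in gset]
        down_pool = [g for g, a in truth.archetype.items()
                     if a is not None and ARCHETYPE_SIGNS[a] < 0 and g in gset]
    sets: dict[str, set] = {}
    n_planted = int(round(gb.frac_planted * gb.set_size))
    for direction, pool in (("up", up_pool), ("down", down_pool)):
        for i in range(gb.planted_per_direction):
            if len(pool) < n_planted:
                raise ValueError(f"not enough planted {direction} genes for sets")
            name = f"planted_{direction}_{i + 1}"
            core = rng.choice(pool, size=n_planted, replace=False)
            filler = rng.choice(genes, size=gb.set_size - n_planted, replace=False)
            sets[name] = set(core) | set(filler)
            truth.set_direction[name] = direction
    for m, targets in truth.mirna_targets.items():
        name = f"planted_targets_{m}"
        sets[name] = set(targets)
        truth.set_direction[name] = "down"
    n_random = max(0, gb.n_sets - len(sets))
    for i in range(n_random):
        name = f"random_{i + 1}"
        sets[name] = set(rng.choice(genes, size=gb.set_size, replace=False))
        truth.set_direction[name] = None
    return GeneSetCollection(sets, provenance="synthetic")


def emit_orthomap(config: SimConfig) -> OrthologMap:
    """Human<->zebrafish style map over the synthetic universes:
    hsg_i <-> drg_i for all genes, plus a second zebrafish ortholog for
    a ``one2many_frac`` fraction of human genes."""
    rng = _rng(config, "orthomap")
    rows = []
    extra = rng.random(config.n_genes) < config.one2many_frac
    for i in range(config.n_genes):
        rows.append((f"hsg{i:05d}", f"drg{i:05d}"))
        if extra[i]:
            rows.append((f"hsg{i:05d}", f"drg{(i + 1) % config.n_genes:05d}"))
    return OrthologMap(pd.DataFrame(rows, columns=["gene_a", "gene_b"]))


def emit_targets(config: SimConfig, truth: SimTruth, genes=None) -> pd.DataFrame:
    """TargetScan-like predicted-target table: planted interactions get
    context scores < -0.2 (U(-0.5, -0.25)); decoy predictions split
    between plausible scores < -0.2 on uncoupled pairs and weak scores
    >= -0.2."""
    mb = config.mirna_block
    rng = _rng(config, "targets")
    if genes is None:
        genes = sorted(truth.tumor_lfc) if truth.tumor_lfc else sorted(truth.archetype)
    genes = list(genes)
    mirnas = sorted(truth.mirna_targets) + [
        f"miR-{i + 1}" for i in range(mb.n_repressive, mb.n_repressive + mb.n_decoy)
    ]
    rows = []
    planted = set()
    for m, targets in truth.mirna_targets.items():
        for g in targets:
            rows.append((m, g, float(rng.uniform(-0.5, -0.25))))
            planted.add((m, g))
    for _ in range(mb.n_decoy_predicted):
        m = mirnas[rng.integers(len(mirnas))]
        g = genes[rng.integers(len(genes))]
        if (m, g) in planted:
            continue
        score = float(rng.uniform(-0.45, -0.21)) if rng.random() < 0.5 else float(
            rng.uniform(-0.19, 0.0)
        )
        rows.append((m, g, score))
    df = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "context_score"])
    return df.drop_duplicates(subset=["mirna_id", "gene_id"]).reset_index(drop=True)
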