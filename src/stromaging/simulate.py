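"""Synthetic expression data with the structure the analysis assumes.

The generator emulates a small two-group microarray study: gene-wise
Gaussian log2 intensities around a per-gene baseline, a sparse set of
strongly differentially expressed genes, optional *modules* — designated
gene sets whose members all receive the same sub-threshold coordinated
shift in one group (the situation where set-level enrichment detects
what single-gene fold changes miss) — and optional many-probes-per-gene
redundancy.  Defaults mirror the study design: 9 young vs 8 old samples,
~2000 genes, residual sd 0.3 on the log2 scale.

Everything is reproducible from the mandatory seed; no global random
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genesets import GeneSet, GeneSetCollection


@dataclass(frozen=True)
class ModuleSpec:
    """A coordinated sub-threshold shift applied to a designated set."""

    set_name: str
    set_size: int
    log2_shift: float  # added to every member, in the stated group
    direction: str = "old"  # which group receives the shift

    def __post_init__(self) -> None:
        if self.direction not in ("old", "young"):
            raise ValueError(f"direction must be 'old' or 'young': {self.direction!r}")
        if self.set_size < 1:
            raise ValueError("set_size must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    All intensity parameters are in log2 units.  `de_fraction` of the
    genes receive a strong group effect of magnitude `de_log2fc`
    (random sign, applied to the old group); module members receive
    their spec's coordinated shift instead.
    """

    seed: int
    n_genes: int = 2000
    n_young: int = 9
    n_old: int = 8
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.3
    de_fraction: float = 0.0
    de_log2fc: float = 1.0
    module_specs: tuple[ModuleSpec, ...] = field(default_factory=tuple)
    probes_per_gene: int = 1

    def __post_init__(self) -> None:
        if self.n_young < 2 or self.n_old < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.baseline_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must be in [0, 1)")
        if self.de_fraction > 0 and self.de_log2fc == 0:
            raise ValueError("de_log2fc must be nonzero when de_fraction > 0")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        total_module = sum(m.set_size for m in self.module_specs)
        n_de = round(self.de_fraction * self.n_genes)
        if total_module + n_de > self.n_genes:
            raise ValueError("module sizes plus DE genes exceed n_genes")


@dataclass(frozen=True)
class GroundTruth:
    """What was injected: DE genes with direction, module membership."""

    de_genes: dict[str, str]  # symbol -> up_in_old | up_in_young
    module_members: dict[str, tuple[str, ...]]
    config: SimulationConfig

    def as_dict(self) -> dict:
        d = {
            "de_genes": dict(self.de_genes),
            "module_members": {k: list(v) for k, v in self.module_members.items()},
            "config": asdict(self.config),
        }
        d["config"]["module_specs"] = [asdict(m) for m in self.config.module_specs]
        return d


def simulate(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth, GeneSetCollection]:
    """Draw one synthetic study.

    Returns the (probe-level, if ``probes_per_gene > 1``) expression
    matrix with group labels and symbol annotation, the injected ground
    truth, and the module gene sets as a collection (empty collection
    when no modules are specified).
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    width = max(4, len(str(G)))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, G + 1)], dtype=object)

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=G)

    # pick disjoint DE and module genes
    n_de = round(config.de_fraction * G)
    n_module = sum(m.set_size for m in config.module_specs)
    special = rng.choice(G, size=n_de + n_module, replace=False)
    de_idx = special[:n_de]
    de_sign = rng.choice([-1.0, 1.0], size=n_de)  # sign of the old-group shift

    module_members: dict[str, tuple[str, ...]] = {}
    module_shift_old = np.zeros(G)
    offset = n_de
    for spec in config.module_specs:
        idx = special[offset : offset + spec.set_size]
        offset += spec.set_size
        shift = spec.log2_shift if spec.direction == "old" else -spec.log2_shift
        module_shift_old[idx] += shift
        module_members[spec.set_name] = tuple(sorted(genes[idx]))

    old_shift = module_shift_old.copy()
    old_shift[de_idx] += de_sign * config.de_log2fc

    n_samples = config.n_young + config.n_old
    sample_ids = [f"Y{i+1}" for i in range(config.n_young)] + [
        f"O{i+1}" for i in range(config.n_old)
    ]
    groups = pd.Series(
        ["young"] * config.n_young + ["old"] * config.n_old, index=sample_ids
    )

    mean = np.tile(baselines[:, None], (1, n_samples))
    mean[:, config.n_young :] += old_shift[:, None]
    gene_values = mean + rng.normal(0.0, config.noise_sd, size=(G, n_samples))

    if config.probes_per_gene == 1:
        values = pd.DataFrame(gene_values, index=genes, columns=sample_ids)
        symbols = pd.Series(genes, index=genes, dtype="string")
    else:
        k = config.probes_per_gene
        probe_ids = np.array(
            [f"{g}_P{j+1}" for g in genes for j in range(k)], dtype=object
        )
        probe_sym = np.repeat(genes, k)
        jitter = rng.normal(0.0, config.noise_sd / 2.0, size=(G * k, n_samples))
        values = pd.DataFrame(
            np.repeat(gene_values, k, axis=0) + jitter,
            index=probe_ids,
            columns=sample_ids,
        )
        symbols = pd.Series(probe_sym, index=probe_ids, dtype="string")

    matrix = ExpressionMatrix(values, groups, symbols)
    truth = GroundTruth(
        de_genes={
            genes[i]: ("up_in_old" if s > 0 else "up_in_young")
            for i, s in zip(de_idx, de_sign)
        },
        module_members=module_members,
        config=config,
    )
    sets = GeneSetCollection(
        tuple(
            GeneSet(name=name, symbols=members, description="injected module")
            for name, members in module_members.items()
        )
    )
    return matrix, truth, sets


@dataclass(frozen=True)
class CalibrationReport:
    """Observed type-I rates on null (no-effect) replicates."""

    n_reps: int
    alpha: float
    de_call_rate: float
    wilcoxon_rate: float
    gsea_rate: float
    gsea_pvalues: tuple[float, ...]

    def summary(self) -> str:
        if self.n_reps == 0:
            return "Null calibration: no replicates run"
        return (
            f"Null calibration over {self.n_reps} replicates (alpha={self.alpha})\n"
            f"  |FC| >= 1.5 call rate : {self.de_call_rate:.4f}\n"
            f"  Wilcoxon p < alpha    : {self.wilcoxon_rate:.4f}\n"
            f"  set-level p < alpha   : {self.gsea_rate:.4f}"
        )


def null_battery(
    config: SimulationConfig,
    n_reps: int,
    alpha: float = 0.05,
    set_size: int = 10,
    n_perm: int = 200,
) -> CalibrationReport:
    """Type-I-error check of the whole stack on effect-free data.

    Each replicate simulates a null study (the config must inject no
    effects), fits the differential-expression model, records the
    fraction of genes called DE and the fraction of Wilcoxon p-values
    below `alpha`, and runs one random-set enrichment test.
    """
    if config.de_fraction > 0 or config.module_specs:
        raise ValueError("null_battery requires a config without injected effects")
    if n_reps == 0:
        return CalibrationReport(0, alpha, float("nan"), float("nan"), float("nan"), ())

    from .diffexp import run_diffexp
    from .gsea import permutation_test, rank_genes

    de_rates, wil_rates, gsea_ps = [], [], []
    master = np.random.default_rng(config.seed)
    for rep in range(n_reps):
        rep_seed = int(master.integers(2**31))
        rep_config = SimulationConfig(
            **{**asdict(config), "module_specs": config.module_specs, "seed": rep_seed}
        )
        matrix, _, _ = simulate(rep_config)
        results = run_diffexp(matrix.collapse_probes())
        t = results.table
        de_rates.append(float(t["is_de"].mean()))
        wil_rates.append(float((t["wilcoxon_p"] < alpha).mean()))
        ranked = rank_genes(results)
        rng = np.random.default_rng(rep_seed + 1)
        random_set = frozenset(
            rng.choice(np.array(ranked.symbols, dtype=object), set_size, replace=False)
        )
        gsea_ps.append(
            permutation_test(
                ranked, random_set, n_perm=n_perm, seed=rep_seed + 2
            )
        )
    gsea_ps_arr = np.array(gsea_ps)
    return CalibrationReport(
        n_reps=n_reps,
        alpha=alpha,
        de_call_rate=float(np.mean(de_rates)),
        wilcoxon_rate=float(np.mean(wil_rates)),
        gsea_rate=float(np.mean(gsea_ps_arr < alpha)),
        gsea_pvalues=tuple(float(p) for p in gsea_ps),
    )
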