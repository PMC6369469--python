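"""Synthetic two-group lncRNA/mRNA array data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, on a log-normal intensity model:

    log2 intensity = probe baseline + group effect + latent module factor
                     + Gaussian noise,

exponentiated to the linear scale.  A probe planted as differentially
expressed with true fold change f gets a +/- log2(f) case-group shift, so
its expected linear group-mean ratio is exactly f (the log-normal noise
factors cancel between groups).  Probes sharing a planted module load a
per-sample standard-normal latent factor, giving pairwise correlation
loading^2 / (loading^2 + noise_sd^2) without specifying a covariance
matrix.  Term and TF-target databases are sampled from the mRNA symbol
universe; each planted module designates one TF whose target set covers
>= 80% of the module's mRNA symbols, so enrichment recovery is testable.

All randomness flows from one seed through deterministically spawned
sub-streams, so a fixed seed gives byte-identical TSV/GMT/JSON outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from lncnet.enrich import GeneSet, GeneSetDB
from lncnet.preprocess import ExpressionMatrix, ProbeAnnotation


def lnc_probe_id(i: int) -> str:
    return f"LNC{i + 1:05d}"


def mrna_probe_id(i: int) -> str:
    return f"MRNA{i + 1:05d}"


def mrna_symbol(i: int) -> str:
    return f"Gm{i + 1:05d}"


@dataclass(frozen=True)
class PlantedDE:
    probe_id: str
    fold_change: float  # true linear fold change, >= 1
    direction: str      # 'up' | 'down'


@dataclass(frozen=True)
class PlantedModule:
    """A coexpression block: lncRNAs and mRNAs sharing one latent factor."""

    lnc_ids: tuple[str, ...]
    mrna_ids: tuple[str, ...]
    loading: float  # in [0, 1]


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror a three-arrays-per-group single-channel design with
    moderate biological noise (0.25 on log2 scale).
    """

    n_lnc_probes: int
    n_mrna_probes: int
    n_per_group: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.25
    planted_de: tuple[PlantedDE, ...] = ()
    planted_modules: tuple[PlantedModule, ...] = ()
    n_terms: int = 60
    term_size_range: tuple[int, int] = (10, 40)
    n_tfs: int = 30
    tf_target_size_range: tuple[int, int] = (10, 40)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_lnc_probes", "n_mrna_probes", "n_per_group", "n_terms", "n_tfs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.baseline_log2_sd < 0 or self.noise_log2_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        known = set(self.all_probe_ids())
        directions: dict[str, str] = {}
        for d in self.planted_de:
            if d.fold_change < 1:
                raise ValueError(f"planted fold change must be >= 1, got {d.fold_change}")
            if d.direction not in ("up", "down"):
                raise ValueError(f"direction must be up|down, got {d.direction!r}")
            if d.probe_id not in known:
                raise ValueError(f"planted DE probe {d.probe_id!r} does not exist")
            prev = directions.setdefault(d.probe_id, d.direction)
            if prev != d.direction:
                raise ValueError(f"probe {d.probe_id!r} planted in conflicting directions")
        for mod in self.planted_modules:
            if not (0.0 <= mod.loading <= 1.0):
                raise ValueError(f"module loading must lie in [0, 1], got {mod.loading}")
            for pid in (*mod.lnc_ids, *mod.mrna_ids):
                if pid not in known:
                    raise ValueError(f"module probe {pid!r} does not exist")
        for lo, hi in (self.term_size_range, self.tf_target_size_range):
            if not (0 < lo <= hi):
                raise ValueError("size ranges must satisfy 0 < min <= max")
        if max(self.term_size_range[1], self.tf_target_size_range[1]) > self.n_mrna_probes:
            raise ValueError("term/TF set sizes exceed the mRNA gene universe")

    def all_probe_ids(self) -> list[str]:
        return [lnc_probe_id(i) for i in range(self.n_lnc_probes)] + [
            mrna_probe_id(i) for i in range(self.n_mrna_probes)
        ]


@dataclass
class GroundTruth:
    """What was planted: the answer key the analysis should recover."""

    true_de: frozenset[tuple[str, str, float]]          # (probe, direction, FC)
    true_coexpr_pairs: frozenset[tuple[str, str, str]]  # (lnc, mrna, sign)
    tf_planted_links: frozenset[tuple[str, str]]        # (tf name, lnc id)

    def fold_change_of(self, probe_id: str) -> tuple[float, str]:
        """(true FC, direction) for a probe; unplanted probes are (1.0, 'up')."""
        for pid, direction, fc in self.true_de:
            if pid == probe_id:
                return fc, direction
        return 1.0, "up"

    def to_json(self, path) -> None:
        payload = {
            "true_de": sorted([list(x) for x in self.true_de]),
            "true_coexpr_pairs": sorted([list(x) for x in self.true_coexpr_pairs]),
            "tf_planted_links": sorted([list(x) for x in self.tf_planted_links]),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            true_de=frozenset((p, dr, float(fc)) for p, dr, fc in d["true_de"]),
            true_coexpr_pairs=frozenset(tuple(x) for x in d["true_coexpr_pairs"]),
            tf_planted_links=frozenset(tuple(x) for x in d["tf_planted_links"]),
        )


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def simulate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ProbeAnnotation, GeneSetDB, GeneSetDB, GroundTruth]:
    """Generate (expression, annotation, term DB, TF-target DB, ground truth)."""
    config.validate()
    rngs = _streams(config.seed, ["baseline", "factor", "noise", "terms", "tfs"])

    lnc_ids = [lnc_probe_id(i) for i in range(config.n_lnc_probes)]
    mrna_ids = [mrna_probe_id(i) for i in range(config.n_mrna_probes)]
    probe_ids = lnc_ids + mrna_ids
    n_probes = len(probe_ids)
    n_samples = 2 * config.n_per_group
    sample_ids = [f"case_{i + 1}" for i in range(config.n_per_group)] + [
        f"ctrl_{i + 1}" for i in range(config.n_per_group)
    ]
    groups = {s: ("case" if s.startswith("case") else "control") for s in sample_ids}
    is_case = np.array([groups[s] == "case" for s in sample_ids])

    idx = {p: i for i, p in enumerate(probe_ids)}
    baseline = rngs["baseline"].normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=n_probes
    )
    log2x = np.tile(baseline[:, None], (1, n_samples))

    # planted group effects: whole log2(FC) shift applied to the case group
    for d in config.planted_de:
        shift = math.log2(d.fold_change)
        if d.direction == "down":
            shift = -shift
        log2x[idx[d.probe_id], is_case] += shift

    # shared latent factor per module, drawn per sample
    for mod in config.planted_modules:
        factor = rngs["factor"].standard_normal(n_samples)
        for pid in (*mod.lnc_ids, *mod.mrna_ids):
            log2x[idx[pid], :] += mod.loading * factor

    if config.noise_log2_sd > 0:
        log2x += rngs["noise"].normal(0.0, config.noise_log2_sd, size=log2x.shape)

    values = pd.DataFrame(np.exp2(log2x), index=probe_ids, columns=sample_ids)
    matrix = ExpressionMatrix(values=values, groups=groups, scale="linear")

    symbol = {p: p for p in lnc_ids}
    symbol.update({mrna_probe_id(i): mrna_symbol(i) for i in range(config.n_mrna_probes)})
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "molecule_type": ["lncRNA"] * len(lnc_ids) + ["mRNA"] * len(mrna_ids),
                "gene_symbol": [symbol[p] for p in probe_ids],
            }
        )
    )

    universe = [mrna_symbol(i) for i in range(config.n_mrna_probes)]
    term_db = _sample_gene_sets(
        rngs["terms"], universe, config.n_terms, config.term_size_range,
        id_prefix="TERM", categories=("GO_BP", "GO_CC", "GO_MF", "KEGG"),
    )
    tf_db = _sample_tf_db(rngs["tfs"], universe, config, symbol)

    truth = GroundTruth(
        true_de=frozenset(
            (d.probe_id, d.direction, float(d.fold_change)) for d in config.planted_de
        ),
        true_coexpr_pairs=frozenset(
            (l, m, "positive")
            for mod in config.planted_modules
            for l in mod.lnc_ids
            for m in mod.mrna_ids
        ),
        tf_planted_links=frozenset(
            (_planted_tf_name(i), l)
            for i, mod in enumerate(config.planted_modules)
            for l in mod.lnc_ids
        ),
    )
    return matrix, annotation, term_db, tf_db, truth


def _planted_tf_name(module_index: int) -> str:
    return f"TF{module_index + 1:04d}"


def _sample_gene_sets(rng, universe, n_sets, size_range, id_prefix, categories) -> GeneSetDB:
    lo, hi = size_range
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sid = f"{id_prefix}{i + 1:04d}"
        sets.append(
            GeneSet(sid, sid, categories[i % len(categories)],
                    frozenset(universe[j] for j in members))
        )
    return GeneSetDB(sets)


def _sample_tf_db(rng, universe, config: SimConfig, symbol) -> GeneSetDB:
    """TF target sets; the first len(planted_modules) TFs cover their module."""
    lo, hi = config.tf_target_size_range
    uni_index = {g: j for j, g in enumerate(universe)}
    sets = []
    for i in range(config.n_tfs):
        sid = f"TF{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i < len(config.planted_modules):
            mod = config.planted_modules[i]
            core = sorted({symbol[m] for m in mod.mrna_ids})
            n_core = max(1, math.ceil(0.8 * len(core)))
            pick = rng.choice(len(core), size=n_core, replace=False)
            members = {core[j] for j in pick}
            pool = [g for g in universe if g not in members]
            extra = max(0, size - len(members))
            if extra:
                more = rng.choice(len(pool), size=min(extra, len(pool)), replace=False)
                members |= {pool[j] for j in more}
        else:
            chosen = rng.choice(len(universe), size=size, replace=False)
            members = {universe[j] for j in chosen}
        sets.append(GeneSet(sid, sid, "TF", frozenset(members)))
    return GeneSetDB(sets)


def simulate_qpcr_ct(
    truth: GroundTruth,
    selected: Sequence[str],
    n_per_group: int = 3,
    reference_gene: str = "GAPDH",
    reference_ct: float = 20.0,
    base_target_ct: float = 26.0,
    noise_ct_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table (gene, sample, group, Ct) for selected probes plus a reference.

    Under the ideal-efficiency model one fold change halves one cycle:
    an up-regulated probe with true FC f has its case-group Ct lowered by
    log2(f) relative to control, so 2^-ddCt recovers f exactly at zero
    noise.  The reference gene has equal expected Ct in both groups.
    """
    if not selected:
        raise ValueError("empty qPCR selection")
    planted = {pid for pid, _, _ in truth.true_de}
    module_probes = {p for l, m, _ in truth.true_coexpr_pairs for p in (l, m)}
    known = planted | module_probes
    for pid in selected:
        if known and pid not in known:
            raise ValueError(f"selected probe {pid!r} absent from ground truth")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = [("case", f"case_{i + 1}") for i in range(n_per_group)] + [
        ("control", f"ctrl_{i + 1}") for i in range(n_per_group)
    ]
    rows = []
    for group, sample in samples:
        ct = reference_ct + (rng.normal(0, noise_ct_sd) if noise_ct_sd > 0 else 0.0)
        rows.append({"gene": reference_gene, "sample": sample, "group": group, "Ct": ct})
    for pid in selected:
        fc, direction = truth.fold_change_of(pid)
        shift = math.log2(fc) * (-1.0 if direction == "up" else 1.0)
        for group, sample in samples:
            ct = base_target_ct + (shift if group == "case" else 0.0)
            if noise_ct_sd > 0:
                ct += rng.normal(0, noise_ct_sd)
            rows.append({"gene": pid, "sample": sample, "group": group, "Ct": ct})
    return pd.DataFrame(rows, columns=["gene", "sample", "group", "Ct"])


def write_ct_table(t: pd.DataFrame, path) -> None:
    t.to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- canonical demo scenario ---------------------------------------------------

def example_config(
    seed: int = 0,
    n_lnc: int = 300,
    n_mrna: int = 800,
    noise_log2_sd: float = 0.25,
    n_modules: int = 5,
    lnc_per_module: int = 2,
    mrna_per_module: int = 8,
    loading: float = 0.95,
) -> SimConfig:
    """A realistic default scenario: planted DE probes and coexpression modules.

    The first lncRNAs/mRNAs carry planted two-group fold changes between 2
    and 10; module members double as DE probes so the top-k selections feed
    non-trivial networks, mirroring how the analysis chains together.
    """
    planted: list[PlantedDE] = []
    fcs = [2.5, 4.0, 6.0, 8.0, 10.0]
    # planted counts scale down with the array so small demo datasets stay valid
    n_de_lnc = min(40, n_lnc // 2)
    n_de_mrna = min(20, n_mrna // 4)
    n_modules = max(0, min(n_modules,
                           n_lnc // lnc_per_module,
                           (n_mrna - n_de_mrna) // mrna_per_module))
    for i in range(n_de_lnc):
        direction = "up" if i % 2 == 0 else "down"
        planted.append(PlantedDE(lnc_probe_id(i), fcs[i % len(fcs)], direction))
    for i in range(n_de_mrna):
        direction = "up" if i % 2 == 0 else "down"
        planted.append(PlantedDE(mrna_probe_id(i), fcs[(i + 2) % len(fcs)], direction))

    modules: list[PlantedModule] = []
    for m in range(n_modules):
        lncs = tuple(lnc_probe_id(i) for i in range(m * lnc_per_module, (m + 1) * lnc_per_module))
        mrnas = tuple(
            mrna_probe_id(n_de_mrna + m * mrna_per_module + j) for j in range(mrna_per_module)
        )
        modules.append(PlantedModule(lncs, mrnas, loading))

    return SimConfig(
        n_lnc_probes=n_lnc,
        n_mrna_probes=n_mrna,
        noise_log2_sd=noise_log2_sd,
        planted_de=tuple(planted),
        planted_modules=tuple(modules),
        n_terms=60,
        term_size_range=(10, 40),
        n_tfs=30,
        tf_target_size_range=(10, 40),
        seed=seed,
    )
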