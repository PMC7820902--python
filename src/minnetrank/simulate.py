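"""Synthetic networks and multi-omics cohorts with planted driver genes.

The generator emulates the statistical structure the ranking method assumes:
driver genes are network hubs (known cancer genes have elevated in- and
out-degree), they are recurrently mutated across samples, and differential
expression is a downstream consequence of mutation — in a sample carrying a
mutated driver, the driver and its first network neighbors shift expression
relative to the matched normal. Effects are planted on first neighbors only;
recovering multi-hop signal is the diffusion's job, keeping fixture and
method independent. Survival is exponential with an elevated hazard for
samples carrying at least two mutated drivers.

Everything is reproducible from a single seed, and every table round-trips
through the plain-text writers/readers below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import InteractionNetwork, load_network
from .omics import VariantRecord, read_maf
from .stratify import load_survival

#: default cohort conditions, frozen after the calibration run shipped with the tests
DEFAULT_N_GENES = 200
DEFAULT_N_DRIVERS = 5
DEFAULT_N_SAMPLES = 100
DEFAULT_MEAN_DEGREE = 4.0
DEFAULT_HUB_FRACTION = 0.05
DEFAULT_MUTATION_RATE_BG = 0.01
DEFAULT_DRIVER_MUT_PROB = 0.4
DEFAULT_DE_EFFECT = 2.0
DEFAULT_NOISE_SD = 0.5
DEFAULT_CENSOR_RATE = 0.3

_VARIANT_CLASS_PROBS = {
    "missense": 0.55,
    "stop_gain": 0.10,
    "frameshift": 0.10,
    "nonframeshift": 0.05,
    "synonymous": 0.20,
}


@dataclass(frozen=True)
class CohortFixture:
    """A complete simulated study: network, omics, survival, and the answer key."""

    network: InteractionNetwork
    planted_drivers: tuple[str, ...]
    variants: tuple[VariantRecord, ...] = field(repr=False)
    tumor_expr: pd.DataFrame = field(repr=False)
    normal_expr: pd.DataFrame = field(repr=False)
    pairing: dict[str, str] = field(repr=False)
    survival: pd.DataFrame = field(repr=False)
    seed: int

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.tumor_expr.columns)


def simulate_network(
    n_genes: int = DEFAULT_N_GENES,
    mean_degree: float = DEFAULT_MEAN_DEGREE,
    hub_fraction: float = DEFAULT_HUB_FRACTION,
    seed: int = 0,
) -> InteractionNetwork:
    """Directed random graph in which a small hub set has elevated degree.

    ``mean_degree`` is the expected number of edges per gene, so the target
    edge count is ``n_genes * mean_degree``. Hub genes (the lexicographically
    first ``ceil(hub_fraction * n_genes)``) are favored as both sources and
    targets, mimicking the high connectivity of known cancer genes.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    n_hubs = max(1, int(np.ceil(hub_fraction * n_genes)))
    weights = np.ones(n_genes)
    weights[:n_hubs] = 10.0
    p = weights / weights.sum()
    target_edges = int(round(n_genes * mean_degree))
    edges: set[tuple[str, str]] = set()
    attempts = 0
    while len(edges) < target_edges and attempts < 50 * target_edges:
        u, v = rng.choice(n_genes, size=2, replace=False, p=p)
        edges.add((genes[u], genes[v]))
        attempts += 1
    if len(edges) < max(1, target_edges // 2):
        raise ValueError("failed to generate enough edges; relax the parameters")
    return InteractionNetwork.from_edges(edges)


def hub_genes(net: InteractionNetwork, n: int) -> tuple[str, ...]:
    """The ``n`` genes of highest total degree (ties broken lexicographically)."""
    ordered = sorted(
        net.genes, key=lambda g: (-(net.in_degree[g] + net.out_degree[g]), g)
    )
    return tuple(ordered[:n])


def _neighbors(net: InteractionNetwork, gene: str) -> set[str]:
    out = {v for (u, v) in net.edges if u == gene}
    inc = {u for (u, v) in net.edges if v == gene}
    return out | inc


def simulate_cohort(
    net: InteractionNetwork,
    planted_drivers: Sequence[str],
    n_samples: int = DEFAULT_N_SAMPLES,
    mutation_rate_bg: float = DEFAULT_MUTATION_RATE_BG,
    driver_mut_prob: float = DEFAULT_DRIVER_MUT_PROB,
    de_effect: float = DEFAULT_DE_EFFECT,
    noise_sd: float = DEFAULT_NOISE_SD,
    censor_rate: float = DEFAULT_CENSOR_RATE,
    seed: int = 0,
) -> CohortFixture:
    """Simulate mutations, paired tumor/normal expression, and survival.

    Per sample, each planted driver mutates with probability
    ``driver_mut_prob`` and each background gene with ``mutation_rate_bg``.
    Baseline expression is log-normal per gene; in a tumor sample, each
    mutated driver and its first network neighbors receive a log2 shift of
    ``de_effect`` on top of log2-normal noise with SD ``noise_sd``. Survival
    times are exponential; carrying >= 2 mutated drivers triples the hazard.
    Censoring replaces the event with a uniform earlier time at rate
    ``censor_rate``.
    """
    drivers = tuple(planted_drivers)
    unknown = set(drivers) - set(net.genes)
    if unknown:
        raise ValueError(f"planted drivers not in the network: {sorted(unknown)}")
    for name, p in (
        ("mutation_rate_bg", mutation_rate_bg),
        ("driver_mut_prob", driver_mut_prob),
        ("censor_rate", censor_rate),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    genes = list(net.genes)
    width = len(str(n_samples))
    samples = [f"S{j + 1:0{width}d}" for j in range(n_samples)]
    driver_set = set(drivers)
    neighbor_map = {d: _neighbors(net, d) for d in drivers}

    classes = list(_VARIANT_CLASS_PROBS)
    class_p = np.array([_VARIANT_CLASS_PROBS[c] for c in classes])

    variants: list[VariantRecord] = []
    mutated_drivers_per_sample: dict[str, set[str]] = {}
    for s in samples:
        mutated: set[str] = set()
        for g in genes:
            p_mut = driver_mut_prob if g in driver_set else mutation_rate_bg
            if rng.random() < p_mut:
                mutated.add(g)
                vclass = classes[rng.choice(len(classes), p=class_p)]
                variants.append(
                    VariantRecord(sample=s, gene=g, variant_class=vclass,
                                  score=float(np.round(rng.uniform(), 4)))
                )
        mutated_drivers_per_sample[s] = mutated & driver_set

    # expression: shared per-gene log-normal baseline, paired normals
    baseline = np.exp2(rng.normal(loc=np.log2(50.0), scale=1.5, size=len(genes)))
    tumor = np.zeros((len(genes), n_samples))
    normal = np.zeros((len(genes), n_samples))
    gidx = {g: i for i, g in enumerate(genes)}
    for j, s in enumerate(samples):
        shift = np.zeros(len(genes))
        for d in mutated_drivers_per_sample[s]:
            for g in neighbor_map[d] | {d}:
                shift[gidx[g]] = de_effect
        noise_t = rng.normal(0.0, noise_sd, size=len(genes))
        noise_n = rng.normal(0.0, noise_sd, size=len(genes))
        tumor[:, j] = baseline * np.exp2(shift + noise_t)
        normal[:, j] = baseline * np.exp2(noise_n)
    normal_samples = [f"{s}N" for s in samples]
    tumor_expr = pd.DataFrame(tumor, index=genes, columns=samples)
    normal_expr = pd.DataFrame(normal, index=genes, columns=normal_samples)
    pairing = dict(zip(samples, normal_samples))

    # survival: exponential, hazard tripled for samples with >= 2 mutated drivers
    base_hazard = 1.0 / 1000.0
    times, events = [], []
    for s in samples:
        hazard = base_hazard * (3.0 if len(mutated_drivers_per_sample[s]) >= 2 else 1.0)
        t = rng.exponential(1.0 / hazard)
        if rng.random() < censor_rate:
            times.append(t * rng.uniform())
            events.append(0)
        else:
            times.append(t)
            events.append(1)
    survival = pd.DataFrame(
        {"sample": samples, "time": np.round(times, 2), "event": events}
    )

    return CohortFixture(
        network=net,
        planted_drivers=drivers,
        variants=tuple(variants),
        tumor_expr=tumor_expr.round(4),
        normal_expr=normal_expr.round(4),
        pairing=pairing,
        survival=survival,
        seed=seed,
    )


def default_fixture(seed: int = 0) -> CohortFixture:
    """The default study conditions: 200 genes, 5 hub drivers, 100 samples."""
    net_seed, cohort_seed = np.random.SeedSequence(seed).generate_state(2) >> 1
    net = simulate_network(seed=int(net_seed))
    drivers = hub_genes(net, DEFAULT_N_DRIVERS)
    return simulate_cohort(net, drivers, seed=int(cohort_seed))


# ---------------------------------------------------------------------------
# plain-text writers / readers (all round-trip)

def write_fixture(fixture: CohortFixture, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "maf": out / "mutations.maf",
        "tumor_expr": out / "tumor_expr.tsv",
        "normal_expr": out / "normal_expr.tsv",
        "pairing": out / "pairing.tsv",
        "survival": out / "survival.tsv",
        "drivers": out / "planted_drivers.txt",
    }
    with open(paths["network"], "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(fixture.network.edges):
            fh.write(f"{u}\t{v}\n")
    maf = pd.DataFrame(
        {
            "Tumor_Sample_Barcode": [v.sample for v in fixture.variants],
            "Hugo_Symbol": [v.gene for v in fixture.variants],
            "Variant_Classification": [v.variant_class for v in fixture.variants],
            "Weight_Score": [v.score for v in fixture.variants],
        }
    )
    maf.to_csv(paths["maf"], sep="\t", index=False)
    fixture.tumor_expr.to_csv(paths["tumor_expr"], sep="\t", index_label="gene")
    fixture.normal_expr.to_csv(paths["normal_expr"], sep="\t", index_label="gene")
    with open(paths["pairing"], "w") as fh:
        fh.write("tumor_sample\tnormal_sample\n")
        for t, n in fixture.pairing.items():
            fh.write(f"{t}\t{n}\n")
    fixture.survival.to_csv(paths["survival"], sep="\t", index=False)
    paths["drivers"].write_text("".join(f"{g}\n" for g in fixture.planted_drivers))
    return paths


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_pairing(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_fixture(fixture_dir: str | Path, seed: int = -1) -> CohortFixture:
    """Load a fixture previously written by :func:`write_fixture`."""
    d = Path(fixture_dir)
    net = load_network(d / "network.tsv")
    return CohortFixture(
        network=net,
        planted_drivers=tuple(
            (d / "planted_drivers.txt").read_text().split()
        ),
        variants=tuple(read_maf(d / "mutations.maf")),
        tumor_expr=read_expression(d / "tumor_expr.tsv"),
        normal_expr=read_expression(d / "normal_expr.tsv"),
        pairing=read_pairing(d / "pairing.tsv"),
        survival=load_survival(d / "survival.tsv"),
        seed=seed,
    )
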