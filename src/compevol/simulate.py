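"""Synthetic gene tables with the statistical structure of a compartment
abundance/rate study.

The generator draws, per gene: a compartment class; a log-normal protein
abundance whose class means encode the membrane:cytoplasm mean-abundance
ratio (1/5 for the bacterial profile, 1/15 for the yeast profile); a log10
omega that is linear in log10 abundance with class-specific slope and
intercept plus Gaussian noise, with a probability of being clamped to a
shared low-rate floor (mimicking rate-estimation software granting all very
low rates the same non-zero number, which makes log omega bimodal); an
essentiality flag linked to abundance through a logistic law; and a
gamma-distributed dS, multiplied by 10 for a small fraction of genes to
plant curation targets. The true class parameters, latent means and outlier
flags are emitted through a separate truth channel, never in the gene table.

The default profiles encode a Simpson-style inversion: class intercepts are
chosen so the raw mean log omega is lowest for Cytoplasm while the class
offsets from the pooled abundance->rate regression are lowest for Membrane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .data import CompartmentClass, GeneRecord

__all__ = [
    "SyntheticParams",
    "default_params",
    "null_params",
    "generate_dataset",
    "write_truth_table",
    "generate_cds_corpus",
    "params_to_dict",
    "params_from_dict",
]

_CLASSES = (CompartmentClass.MEMBRANE, CompartmentClass.CYTOPLASM, CompartmentClass.OTHERS)


@dataclass
class SyntheticParams:
    """Full generative description of one simulated dataset.

    Per-class mappings are keyed by CompartmentClass. ``slope``/``intercept``
    describe E[log10 omega] = intercept + slope * log10 abundance within a
    class; ``floor_prob``/``floor_value`` implement the shared low-rate
    floor; ``essentiality_coefs`` = (b0, b1) of
    P(essential) = logistic(b0 + b1 * log10 abundance).
    """

    n_genes: int
    class_props: Mapping[CompartmentClass, float]
    abund_logmean: Mapping[CompartmentClass, float]
    abund_logsd: Mapping[CompartmentClass, float]
    slope: Mapping[CompartmentClass, float]
    intercept: Mapping[CompartmentClass, float]
    noise_sd: float
    floor_prob: float = 0.08
    floor_value: float = 1e-3
    essentiality_coefs: tuple[float, float] = (-4.0, 1.4)
    ds_shape: float = 4.0
    ds_scale: float = 0.1
    outlier_frac: float = 0.05
    seed: int = 0
    species_tag: str = "synthetic"
    location_labels: Mapping[CompartmentClass, str] = field(
        default_factory=lambda: {
            CompartmentClass.MEMBRANE: "cell membrane",
            CompartmentClass.CYTOPLASM: "cytoplasm",
            CompartmentClass.OTHERS: "nucleolus",
        }
    )

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        total = sum(self.class_props.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class_props must sum to 1, got {total}")
        if any(sd <= 0 for sd in self.abund_logsd.values()) or self.noise_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not 0.0 <= self.floor_prob <= 1.0:
            raise ValueError("floor_prob must lie in [0, 1]")
        if self.floor_value <= 0 or self.ds_shape <= 0 or self.ds_scale <= 0:
            raise ValueError("floor_value, ds_shape, ds_scale must be positive")
        if not 0.0 <= self.outlier_frac <= 1.0:
            raise ValueError("outlier_frac must lie in [0, 1]")


def default_params(profile: str, seed: int = 0) -> SyntheticParams:
    """Study-condition defaults for the two organism-like profiles.

    "ecoli-like": 980 genes, compartment proportions 46.94/42.04/11.02%,
    membrane:cytoplasm mean-abundance ratio 1/5, shallow slopes.
    "yeast-like": 4,104 genes, proportions 26.34/27.95/45.71%, ratio 1/15,
    steeper slopes. Both encode the inversion: raw mean log omega is lowest
    for Cytoplasm while pooled-regression residual offsets are lowest for
    Membrane.
    """
    M, C, O = _CLASSES
    if profile == "ecoli-like":
        mu_c = 2.3
        mu_m = mu_c + math.log10(1 / 5)
        return SyntheticParams(
            n_genes=980,
            class_props={M: 0.4694, C: 0.4204, O: 0.1102},
            abund_logmean={M: mu_m, C: mu_c, O: 2.0},
            abund_logsd={M: 1.0, C: 1.0, O: 1.0},
            # shallow slopes, raw mean log10(omega): M -0.85, C -0.95, O -0.90
            slope={M: -0.16, C: -0.28, O: -0.24},
            intercept={M: -0.85 + 0.16 * mu_m, C: -0.95 + 0.28 * mu_c, O: -0.90 + 0.24 * 2.0},
            noise_sd=0.35,
            floor_prob=0.10,
            essentiality_coefs=(-4.5, 1.2),
            ds_shape=4.0,
            ds_scale=0.08,
            outlier_frac=0.05,
            seed=seed,
            species_tag="ecoli-like",
        )
    if profile == "yeast-like":
        mu_c = 2.5
        mu_m = mu_c + math.log10(1 / 15)
        return SyntheticParams(
            n_genes=4104,
            class_props={M: 0.2634, C: 0.2795, O: 0.4571},
            abund_logmean={M: mu_m, C: mu_c, O: 2.0},
            abund_logsd={M: 1.0, C: 1.0, O: 1.0},
            # steeper slopes, raw mean log10(omega): M -0.55, C -0.85, O -0.70
            slope={M: -0.30, C: -0.45, O: -0.40},
            intercept={M: -0.55 + 0.30 * mu_m, C: -0.85 + 0.45 * mu_c, O: -0.70 + 0.40 * 2.0},
            noise_sd=0.35,
            floor_prob=0.08,
            essentiality_coefs=(-4.0, 1.4),
            ds_shape=4.0,
            ds_scale=0.12,
            outlier_frac=0.05,
            seed=seed,
            species_tag="yeast-like",
        )
    raise ValueError(f"unknown profile {profile!r}; expected 'ecoli-like' or 'yeast-like'")


def null_params(profile: str = "yeast-like", seed: int = 0) -> SyntheticParams:
    """A calibration profile: all classes share one abundance and rate law.

    Under this null every downstream compartment test should reject at its
    nominal level only.
    """
    p = default_params(profile, seed=seed)
    M, C, O = _CLASSES
    mu = p.abund_logmean[C]
    sl = p.slope[C]
    ic = p.intercept[C]
    return SyntheticParams(
        n_genes=p.n_genes,
        class_props=dict(p.class_props),
        abund_logmean={M: mu, C: mu, O: mu},
        abund_logsd={M: 1.0, C: 1.0, O: 1.0},
        slope={M: sl, C: sl, O: sl},
        intercept={M: ic, C: ic, O: ic},
        noise_sd=p.noise_sd,
        floor_prob=p.floor_prob,
        floor_value=p.floor_value,
        essentiality_coefs=p.essentiality_coefs,
        ds_shape=p.ds_shape,
        ds_scale=p.ds_scale,
        outlier_frac=p.outlier_frac,
        seed=seed,
        species_tag=p.species_tag + "-null",
    )


@dataclass
class TruthTable:
    """Hidden per-gene truth: class, latent mean log10 omega, dS outlier flag."""

    gene_id: list
    compartment: list
    latent_log10_omega: np.ndarray
    floored: np.ndarray
    ds_outlier: np.ndarray


def generate_dataset(params: SyntheticParams) -> tuple[list[GeneRecord], TruthTable]:
    """Draw one gene table; fully reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    classes = list(_CLASSES)
    props = np.array([params.class_props[c] for c in classes])
    idx = rng.choice(len(classes), size=n, p=props)

    mu = np.array([params.abund_logmean[c] for c in classes])[idx]
    sd = np.array([params.abund_logsd[c] for c in classes])[idx]
    log_abund = rng.normal(mu, sd)
    abundance = 10.0 ** log_abund

    slope = np.array([params.slope[c] for c in classes])[idx]
    intercept = np.array([params.intercept[c] for c in classes])[idx]
    latent = intercept + slope * log_abund
    log_omega = latent + rng.normal(0.0, params.noise_sd, size=n)
    omega = 10.0 ** log_omega
    floored = rng.random(n) < params.floor_prob
    omega = np.where(floored, params.floor_value, omega)

    b0, b1 = params.essentiality_coefs
    p_ess = 1.0 / (1.0 + np.exp(-(b0 + b1 * log_abund)))
    essential = rng.random(n) < p_ess

    ds = rng.gamma(params.ds_shape, params.ds_scale, size=n)
    n_out = int(round(params.outlier_frac * n))
    outlier = np.zeros(n, dtype=bool)
    if n_out:
        outlier[rng.choice(n, size=n_out, replace=False)] = True
        ds = np.where(outlier, ds * 10.0, ds)

    # dN consistent with omega and ds (omega = dn/ds); cosmetic but keeps
    # the table self-consistent for round-trip tests.
    dn = omega * ds

    records = []
    for i in range(n):
        c = classes[idx[i]]
        records.append(
            GeneRecord(
                gene_id=f"g{i:05d}",
                omega=float(omega[i]),
                dn=float(dn[i]),
                ds=float(ds[i]),
                abundance=float(abundance[i]),
                location_label=params.location_labels[c],
                essential=bool(essential[i]),
                species_tag=params.species_tag,
            )
        )
    truth = TruthTable(
        gene_id=[r.gene_id for r in records],
        compartment=[classes[i].value for i in idx],
        latent_log10_omega=latent,
        floored=floored,
        ds_outlier=outlier,
    )
    return records, truth


def write_truth_table(truth: TruthTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("gene_id\tcompartment\tlatent_log10_omega\tfloored\tds_outlier\n")
        for i, gid in enumerate(truth.gene_id):
            fh.write(
                f"{gid}\t{truth.compartment[i]}\t{truth.latent_log10_omega[i]!r}\t"
                f"{int(truth.floored[i])}\t{int(truth.ds_outlier[i])}\n"
            )


# --- synthetic coding sequences with abundance-linked codon enrichment ----

_STOPS = ("TAA", "TAG", "TGA")


def _synonymous_blocks():
    # local import keeps Biopython optional at data-generation time
    from .codon import synonymous_blocks

    return synonymous_blocks()


def generate_cds_corpus(
    records: Sequence[GeneRecord],
    strength: float = 0.9,
    length: int = 60,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict]:
    """Synthetic CDSs whose codon usage tracks protein abundance.

    For each synonymous block one codon is planted as "optimal"; a gene at
    abundance quantile q in (0,1) uses the planted codon with probability
    1/d + (1 - 1/d) * strength * q (d = block degeneracy), the rest uniform.
    Returns (gene_id, sequence) pairs plus the planted optimal-codon map —
    the truth channel for proxy-validity tests.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    blocks = _synonymous_blocks()
    multi = {aa: codons for aa, codons in blocks.items() if len(codons) > 1 and aa != "*"}
    aas = sorted(multi)
    planted = {aa: multi[aa][rng.integers(len(multi[aa]))] for aa in aas}

    withab = [r for r in records if r.abundance is not None]
    order = np.argsort([r.abundance for r in withab], kind="stable")
    q = np.empty(len(withab))
    q[order] = (np.arange(len(withab)) + 0.5) / len(withab)

    corpus = []
    for r, qi in zip(withab, q):
        aa_seq = [aas[j] for j in rng.integers(len(aas), size=length - 2)]
        codons = ["ATG"]
        for aa in aa_seq:
            block = multi[aa]
            d = len(block)
            p_opt = 1.0 / d + (1.0 - 1.0 / d) * strength * qi
            if rng.random() < p_opt:
                codons.append(planted[aa])
            else:
                others = [c for c in block if c != planted[aa]]
                codons.append(others[rng.integers(len(others))])
        codons.append("TAA")
        corpus.append((r.gene_id, "".join(codons)))
    return corpus, planted


def params_to_dict(params: SyntheticParams) -> dict:
    """YAML/JSON-serializable form of SyntheticParams."""
    d = asdict(params)
    for key in ("class_props", "abund_logmean", "abund_logsd", "slope", "intercept", "location_labels"):
        d[key] = {k.value if isinstance(k, CompartmentClass) else k: v for k, v in d[key].items()}
    d["essentiality_coefs"] = list(d["essentiality_coefs"])
    return d


def params_from_dict(d: Mapping) -> SyntheticParams:
    d = dict(d)
    for key in ("class_props", "abund_logmean", "abund_logsd", "slope", "intercept", "location_labels"):
        if key in d:
            d[key] = {CompartmentClass(k): v for k, v in d[key].items()}
    if "essentiality_coefs" in d:
        d["essentiality_coefs"] = tuple(d["essentiality_coefs"])
    return SyntheticParams(**d)
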