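"""Synthetic multi-compartment CAR T-cell trial generator.

Emulates the statistical structure of a longitudinal intraventricular
CAR-T trial so that every pipeline stage has a parameter-recovery test
against known ground truth:

* multi-patient, multi-cycle repertoires over CSF, blood (PBMC), the
  infused product (cycle 0) and an end-of-therapy tumor resection;
* a heavy-tailed background clone-size law (power law by default,
  symmetric Dirichlet optionally);
* planted expander clonotypes whose expected frequency grows
  geometrically across cycles in CSF only (flat in PBMC);
* a CAR+ T-cell fraction that decays across cycles in CSF, with
  background CAR reads in CAR- cells drawn on {0, 1, 2} so the 3-read
  positivity boundary is genuinely exercised;
* condition-dependent cell-type composition (a planted monocyte shift in
  "response"-window CSF samples);
* a product repertoire disjoint from the patient's endogenous pool, and
  a tumor repertoire seeded preferentially from CSF-expanded clones
  (rate ``tumor_seed_rate_expanded``) over CSF-unexpanded ones;
* a small gene panel whose first ``n_coupled_genes`` genes tie CSF
  pseudobulk means linearly to PBMC pseudobulk means (slope
  ``coupling_slope``), the rest varying independently.

Every clonotype owns one fixed TRA and TRB strict key; a configurable
fraction of cells emit only one chain (exercising the pairing filter), a
small fraction emit doublet-like secondary chains, and a few
non-productive contigs are sprinkled in. All randomness flows from a
single seed through one generator consumed in a fixed order, so a fixed
config is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from itertools import product as iproduct
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import io_ingest
from .clonotype import make_clonotype_id
from .io_ingest import CountMatrix
from .types import CSF, PBMC, PRODUCT, TUMOR, SampleKey, ValidationError

# ------------------------------------------------------------- chain parts

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    b1 + b2 + b3: aa
    for (b1, b2, b3), aa in zip(iproduct(_BASES, _BASES, _BASES), _AA)
}
_SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")

TRAV = [f"TRAV{i}" for i in range(1, 21)]
TRAJ = [f"TRAJ{i}" for i in range(1, 31)]
TRBV = [f"TRBV{i}" for i in range(1, 21)]
TRBD = ["TRBD1", "TRBD2"]
TRBJ = [f"TRBJ{i}" for i in range(1, 14)]

T_STATES = [
    "CD8_effector", "CD8_memory", "CD8_resident_memory", "CD4_effector",
    "CD4_naive", "Treg", "CD8_exhausted", "proliferating",
]
_T_STATE_P_BASE = [0.25, 0.18, 0.10, 0.15, 0.15, 0.07, 0.05, 0.05]
_T_STATE_P_CARPOS = [0.08, 0.05, 0.02, 0.05, 0.05, 0.05, 0.40, 0.30]


def translate(nt: str) -> str:
    return "".join(CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3))


# ------------------------------------------------------------------ config

def _default_cells_per_sample() -> dict:
    return {CSF: 900, PBMC: 600, PRODUCT: 500, TUMOR: 400}


def _default_composition() -> dict:
    blood_like = {"T": 0.55, "NK": 0.12, "B": 0.08, "Mono": 0.15, "DC": 0.05, "Plasma": 0.05}
    return {
        CSF: dict(blood_like),
        PBMC: dict(blood_like),
        PRODUCT: {"T": 1.0},
        TUMOR: {"T": 0.15, "Myeloid": 0.55, "Mono": 0.12, "NK": 0.08, "B": 0.05, "DC": 0.05},
    }


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic trial. Defaults are the
    package's reference conditions; see docs/methods.md for rationale."""

    seed: int = 0
    n_patients: int = 3
    n_cycles: int = 4
    cells_per_sample: dict = field(default_factory=_default_cells_per_sample)
    composition: dict = field(default_factory=_default_composition)
    response_cycles: tuple = (3, 4)  # CSF cycles treated as response windows
    composition_shift: dict = field(default_factory=lambda: {"Mono": 2.0})

    # repertoire
    n_background_clones: int = 300
    clone_law: str = "power"  # "power" or "dirichlet"
    power_exponent: float = 0.3
    dirichlet_alpha: float = 0.05
    n_planted_expanders: int = 5
    planted_initial_freq: float = 0.015
    growth_factor: float = 2.0
    n_product_clones: int = 150

    # CAR transgene
    car_pos_schedule_csf: tuple = (0.4, 0.3, 0.2, 0.1)
    car_pos_fraction_pbmc: float = 0.05
    car_pos_fraction_product: float = 0.7
    car_neg_read_probs: tuple = (0.80, 0.15, 0.05)  # P(reads = 0, 1, 2) in CAR- cells
    car_pos_read_mean_excess: float = 5.0  # CAR+ reads = 3 + Poisson(this)

    # chain emission
    chain_dropout: float = 0.10
    multi_chain_rate: float = 0.05
    nonproductive_rate: float = 0.03

    # gene panel
    n_genes: int = 60
    n_coupled_genes: int = 10
    coupling_slope: float = 2.0
    coupling_noise_sigma: float = 0.1
    gene_mean_log_mu: float = math.log(2.0)
    gene_mean_log_sigma: float = 1.0
    sample_factor_sigma: float = 0.6
    nb_dispersion: float = 5.0

    # tumor seeding
    tumor_seed_rate_expanded: float = 0.15
    tumor_seed_rate_unexpanded: float = 0.002
    n_tumor_private_clones: int = 30
    patients_with_tumor: int = 1  # the first k patients get a tumor sample

    def validate(self) -> None:
        for name in (
            "planted_initial_freq", "chain_dropout", "multi_chain_rate",
            "nonproductive_rate", "car_pos_fraction_pbmc", "car_pos_fraction_product",
            "tumor_seed_rate_expanded", "tumor_seed_rate_unexpanded",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.growth_factor < 1.0:
            raise ValidationError(f"growth_factor must be >= 1, got {self.growth_factor}")
        if len(self.car_pos_schedule_csf) < self.n_cycles:
            raise ValidationError(
                f"car_pos_schedule_csf covers {len(self.car_pos_schedule_csf)} cycles, "
                f"trial has {self.n_cycles}"
            )
        peak = (
            self.n_planted_expanders
            * self.planted_initial_freq
            * self.growth_factor ** (self.n_cycles - 1)
        )
        if peak >= 0.9:
            raise ValidationError(
                f"planted expanders would occupy {peak:.2f} of final-cycle CSF; "
                "infeasible config (limit 0.9)"
            )
        if self.n_planted_expanders > self.cells_per_sample[CSF]:
            raise ValidationError("more planted expanders than CSF cells per sample")
        if abs(sum(p for p in self.car_neg_read_probs) - 1.0) > 1e-9:
            raise ValidationError("car_neg_read_probs must sum to 1")
        for comp, probs in self.composition.items():
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValidationError(f"composition for {comp} must sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        cfg = cls(**d)
        for name in ("response_cycles", "car_pos_schedule_csf", "car_neg_read_probs"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


# ------------------------------------------------------------ ground truth

@dataclass
class GroundTruth:
    planted_expanders: dict  # upn -> list of clonotype ids
    clone_defs: pd.DataFrame  # upn, clonotype_id, planted, pool
    true_car: pd.DataFrame  # barcode, is_car_positive
    coupled_genes: list
    coupling_slope: float
    car_pos_schedule_csf: tuple
    car_pos_fraction_pbmc: float
    tumor_seeding: dict  # upn -> DataFrame(clonotype_id, stratum, seeded)

    def summary_dict(self) -> dict:
        return {
            "planted_expanders": self.planted_expanders,
            "coupled_genes": list(self.coupled_genes),
            "coupling_slope": self.coupling_slope,
            "car_pos_schedule_csf": list(self.car_pos_schedule_csf),
            "car_pos_fraction_pbmc": self.car_pos_fraction_pbmc,
            "tumor_seeding": {
                upn: df.to_dict("records") for upn, df in self.tumor_seeding.items()
            },
        }


@dataclass
class TrialData:
    contigs: pd.DataFrame
    cells: pd.DataFrame
    counts: CountMatrix
    truth: GroundTruth
    config: GeneratorConfig


# --------------------------------------------------------------- generator

def _clone_pool(rng: np.random.Generator, n: int, prefix: str) -> pd.DataFrame:
    """Draw ``n`` clone definitions with unique paired strict keys."""
    seen: set = set()
    rows = []
    while len(rows) < n:
        a_cdr3 = "TGT" + "".join(rng.choice(_SENSE_CODONS, size=11)) + "TTT"
        b_cdr3 = "TGC" + "".join(rng.choice(_SENSE_CODONS, size=12)) + "TTC"
        if (a_cdr3, b_cdr3) in seen:
            continue
        seen.add((a_cdr3, b_cdr3))
        av, aj = rng.choice(TRAV), rng.choice(TRAJ)
        bv, bd, bj = rng.choice(TRBV), rng.choice(TRBD), rng.choice(TRBJ)
        bc = "TRBC1" if rng.random() < 0.5 else "TRBC2"
        alpha_key = f"{av}|{aj}|TRAC|{a_cdr3}"
        beta_key = f"{bv}|{bd}|{bj}|{bc}|{b_cdr3}"
        rows.append(
            dict(
                av=av, aj=aj, ac="TRAC", a_cdr3=a_cdr3, a_aa=translate(a_cdr3),
                bv=bv, bd=bd, bj=bj, bc=bc, b_cdr3=b_cdr3, b_aa=translate(b_cdr3),
                alpha_key=alpha_key, beta_key=beta_key,
                clonotype_id=make_clonotype_id(alpha_key, beta_key),
            )
        )
    df = pd.DataFrame(rows)
    df["name"] = [f"{prefix}{i:04d}" for i in range(n)]
    return df


def _background_weights(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    n = cfg.n_background_clones
    if cfg.clone_law == "power":
        w = np.arange(1, n + 1, dtype=float) ** (-cfg.power_exponent)
    elif cfg.clone_law == "dirichlet":
        w = rng.dirichlet(np.full(n, cfg.dirichlet_alpha))
    else:
        raise ValidationError(f"unknown clone_law {cfg.clone_law!r}")
    return w / w.sum()


def _qc_metrics(rng: np.random.Generator, compartment: str, n: int) -> dict:
    mean_genes = {CSF: 1800, PBMC: 1800, PRODUCT: 2600, TUMOR: 2900}[compartment]
    n_genes = np.clip(np.round(rng.normal(mean_genes, 450, n)), 60, None).astype(int)
    n_counts = np.round(n_genes * rng.uniform(2.2, 3.2, n)).astype(int)
    pct_mito = np.clip(rng.exponential(5.0, n), 0, 100)
    return {"n_genes": n_genes, "n_counts": n_counts, "pct_mito": pct_mito}


def _draw_barcodes(rng: np.random.Generator, n: int, gem_well: int) -> np.ndarray:
    """10x-style unique barcodes; the GEM-well suffix makes them globally
    unique across samples (as in aggregated multi-sample runs)."""
    letters = np.array(list("ACGT"))
    out: list = []
    seen: set = set()
    while len(out) < n:
        block = letters[rng.integers(0, 4, size=(n - len(out), 16))]
        for row in block:
            s = row.tobytes().decode("utf-32-le")
            if s not in seen:
                seen.add(s)
                out.append(f"{s}-{gem_well}")
    return np.asarray(out)


def _car_reads(rng: np.random.Generator, is_pos: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    n = len(is_pos)
    reads = rng.choice([0, 1, 2], size=n, p=list(cfg.car_neg_read_probs))
    n_pos = int(is_pos.sum())
    if n_pos:
        reads[is_pos] = 3 + rng.poisson(cfg.car_pos_read_mean_excess, n_pos)
    return reads


def _emit_contigs(
    rng: np.random.Generator,
    barcodes: np.ndarray,
    clone_idx: np.ndarray,
    clones: pd.DataFrame,
    sample: SampleKey,
    cfg: GeneratorConfig,
) -> pd.DataFrame:
    """Contig rows for the T cells of one sample (with dropout/doublets)."""
    n = len(barcodes)
    drop = rng.random(n) < cfg.chain_dropout
    drop_alpha = rng.random(n) < 0.5  # which chain is lost, when one is
    emit_alpha = ~(drop & drop_alpha)
    emit_beta = ~(drop & ~drop_alpha)
    multi = rng.random(n) < cfg.multi_chain_rate
    nonprod = rng.random(n) < cfg.nonproductive_rate

    c = clones.iloc[clone_idx].reset_index(drop=True)
    frames = []

    def chain_rows(sel, chain, v, d, j, cc, nt, aa, umis, productive=True):
        m = int(sel.sum())
        if m == 0:
            return
        reads = umis[sel] * (15 + rng.poisson(5, m))
        frames.append(
            pd.DataFrame(
                {
                    "upn": sample.upn, "cycle": sample.cycle, "compartment": sample.compartment,
                    "barcode": barcodes[sel], "chain": chain,
                    "v_gene": v[sel], "d_gene": d if isinstance(d, str) else d[sel],
                    "j_gene": j[sel], "c_gene": cc if isinstance(cc, str) else cc[sel],
                    "cdr3_nt": nt[sel], "cdr3_aa": aa[sel],
                    "reads": reads, "umis": umis[sel],
                    "productive": productive, "is_cell": True,
                }
            )
        )

    primary_umis = 2 + rng.poisson(2, n)
    chain_rows(emit_alpha, "TRA", c["av"].to_numpy(), "None", c["aj"].to_numpy(),
               "TRAC", c["a_cdr3"].to_numpy(), c["a_aa"].to_numpy(), primary_umis)
    chain_rows(emit_beta, "TRB", c["bv"].to_numpy(), c["bd"].to_numpy(), c["bj"].to_numpy(),
               c["bc"].to_numpy(), c["b_cdr3"].to_numpy(), c["b_aa"].to_numpy(), primary_umis)

    # doublet-like secondary TRA, always at lower UMI than the primary
    other = clones.iloc[rng.integers(0, len(clones), n)].reset_index(drop=True)
    sec = multi & emit_alpha & (other["a_cdr3"].to_numpy() != c["a_cdr3"].to_numpy())
    chain_rows(sec, "TRA", other["av"].to_numpy(), "None", other["aj"].to_numpy(),
               "TRAC", other["a_cdr3"].to_numpy(), other["a_aa"].to_numpy(),
               np.ones(n, dtype=int))

    # non-productive stray contigs (filtered at clonotype calling)
    chain_rows(nonprod, "TRB", other["bv"].to_numpy(), other["bd"].to_numpy(),
               other["bj"].to_numpy(), other["bc"].to_numpy(), other["b_cdr3"].to_numpy(),
               np.full(n, "None"), np.ones(n, dtype=int), productive=False)

    if not frames:
        return pd.DataFrame(columns=io_ingest.CONTIG_COLUMNS)
    return pd.concat(frames, ignore_index=True)[io_ingest.CONTIG_COLUMNS]


def generate_trial(config: GeneratorConfig) -> TrialData:
    """Generate one complete synthetic trial; see module docstring."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    upns = [f"UPN{i + 1:02d}" for i in range(cfg.n_patients)]

    cell_frames, contig_frames = [], []
    count_blocks, count_barcodes = [], []
    planted_ids: dict = {}
    clone_def_frames = []
    tumor_seeding: dict = {}
    gem_well = 0

    # gene panel (shared across patients)
    base_mean = rng.lognormal(cfg.gene_mean_log_mu, cfg.gene_mean_log_sigma, cfg.n_genes)
    genes = [f"GENE{i:03d}" for i in range(cfg.n_genes)]
    coupled = genes[: cfg.n_coupled_genes]
    coupled_mask = np.zeros(cfg.n_genes, dtype=bool)
    coupled_mask[: cfg.n_coupled_genes] = True

    def nb_counts(mu: np.ndarray, m: int) -> np.ndarray:
        r = cfg.nb_dispersion
        return rng.negative_binomial(r, r / (r + mu), size=(m, cfg.n_genes))

    for pi, upn in enumerate(upns):
        endo = _clone_pool(rng, cfg.n_background_clones + cfg.n_planted_expanders, f"{upn}-endo")
        prod_pool = _clone_pool(rng, cfg.n_product_clones, f"{upn}-prod")
        tumor_private = _clone_pool(rng, cfg.n_tumor_private_clones, f"{upn}-tum")
        bg_w = _background_weights(rng, cfg)
        planted_slice = slice(cfg.n_background_clones, None)
        planted_ids[upn] = endo["clonotype_id"].iloc[planted_slice].tolist()
        for pool_name, pool in (("endogenous", endo), ("product", prod_pool), ("tumor_private", tumor_private)):
            clone_def_frames.append(
                pd.DataFrame(
                    {
                        "upn": upn,
                        "clonotype_id": pool["clonotype_id"],
                        "pool": pool_name,
                        "planted": (pool_name == "endogenous")
                        & pool.index.isin(range(cfg.n_background_clones, len(endo))),
                    }
                )
            )

        def endo_weights(planted_freq: float) -> np.ndarray:
            planted = np.full(cfg.n_planted_expanders, planted_freq)
            return np.concatenate([bg_w * (1 - planted.sum()), planted])

        csf_clone_counts = np.zeros(len(endo), dtype=np.int64)
        csf_max_freq = np.zeros(len(endo), dtype=float)
        csf_freq_rows: list = []  # realized per-cycle frequencies of observed clones

        def sample_t_compartment(sample: SampleKey, weights: np.ndarray, pool: pd.DataFrame,
                                 car_pos_frac: float):
            nonlocal gem_well
            gem_well += 1
            comp = sample.compartment
            n = cfg.cells_per_sample[comp]
            probs = dict(cfg.composition[comp])
            if comp == CSF and sample.cycle in cfg.response_cycles:
                for ct, fold in cfg.composition_shift.items():
                    if ct in probs:
                        probs[ct] *= fold
                z = sum(probs.values())
                probs = {k: v / z for k, v in probs.items()}
            types = list(probs)
            cell_type = rng.choice(types, size=n, p=[probs[t] for t in types])
            barcodes = _draw_barcodes(rng, n, gem_well)
            is_t = cell_type == "T"
            n_t = int(is_t.sum())
            clone_idx = rng.choice(len(pool), size=n_t, p=weights)
            is_pos = np.zeros(n, dtype=bool)
            is_pos[is_t] = rng.random(n_t) < car_pos_frac
            car_reads = np.zeros(n, dtype=int)
            car_reads[is_t] = _car_reads(rng, is_pos[is_t], cfg)
            t_state = np.full(n, None, dtype=object)
            t_state[is_t & is_pos] = rng.choice(T_STATES, size=int((is_t & is_pos).sum()),
                                                p=_T_STATE_P_CARPOS)
            t_state[is_t & ~is_pos] = rng.choice(T_STATES, size=int((is_t & ~is_pos).sum()),
                                                 p=_T_STATE_P_BASE)
            qc = _qc_metrics(rng, comp, n)
            cell_frames.append(
                pd.DataFrame(
                    {
                        "upn": sample.upn, "cycle": sample.cycle, "compartment": comp,
                        "barcode": barcodes, "cell_type": cell_type, "t_state": t_state,
                        "car_reads": car_reads, **qc,
                    }
                )
            )
            contig_frames.append(
                _emit_contigs(rng, barcodes[is_t], clone_idx, pool, sample, cfg)
            )
            return barcodes, clone_idx, is_t

        # product (cycle 0): its own clone pool, disjoint from the
        # endogenous repertoire, so CSF-expanded clones never trace to it
        sample_t_compartment(SampleKey(upn, 0, PRODUCT), _product_weights(cfg),
                             prod_pool, cfg.car_pos_fraction_product)

        for cycle in range(1, cfg.n_cycles + 1):
            # per-(patient, cycle) pseudobulk means; coupled genes tie CSF to PBMC
            mu_pb = base_mean * rng.lognormal(0.0, cfg.sample_factor_sigma, cfg.n_genes)
            mu_ind = base_mean * rng.lognormal(0.0, cfg.sample_factor_sigma, cfg.n_genes)
            noise = rng.lognormal(0.0, cfg.coupling_noise_sigma, cfg.n_genes)
            mu_csf = np.where(coupled_mask, cfg.coupling_slope * mu_pb * noise, mu_ind)

            csf_w = endo_weights(cfg.planted_initial_freq * cfg.growth_factor ** (cycle - 1))
            bcs, cidx, _ = sample_t_compartment(
                SampleKey(upn, cycle, CSF), csf_w, endo,
                cfg.car_pos_schedule_csf[cycle - 1],
            )
            cycle_counts = np.bincount(cidx, minlength=len(endo))
            csf_clone_counts += cycle_counts
            if len(cidx):
                freqs_c = cycle_counts / len(cidx)
                csf_max_freq = np.maximum(csf_max_freq, freqs_c)
                csf_freq_rows.extend(freqs_c[cycle_counts > 0])
            count_blocks.append(sp.csr_matrix(nb_counts(mu_csf, len(bcs)).T))
            count_barcodes.extend(bcs)

            pb_w = endo_weights(cfg.planted_initial_freq)
            bcs, _, _ = sample_t_compartment(
                SampleKey(upn, cycle, PBMC), pb_w, endo, cfg.car_pos_fraction_pbmc
            )
            count_blocks.append(sp.csr_matrix(nb_counts(mu_pb, len(bcs)).T))
            count_barcodes.extend(bcs)

        if pi < cfg.patients_with_tumor:
            observed = csf_clone_counts > 0
            # the seeding stratum uses *realized* expansion — planted clones
            # plus background clones whose best per-cycle frequency reaches
            # the patient's own 80th percentile of realized clone
            # frequencies (with more than one cell overall). This gives an
            # expanded set of realistic size rather than the planted ids
            # alone, mirroring how the analysis defines expansion.
            is_planted = np.zeros(len(endo), dtype=bool)
            is_planted[planted_slice] = True
            freq_cut = np.quantile(np.asarray(csf_freq_rows), 0.80) if csf_freq_rows else np.inf
            is_expanded = is_planted | (
                (csf_clone_counts > 1) & (csf_max_freq >= freq_cut)
            )
            strata = np.where(is_expanded, "expanded", "unexpanded")
            rate = np.where(is_expanded, cfg.tumor_seed_rate_expanded, cfg.tumor_seed_rate_unexpanded)
            seeded = observed & (rng.random(len(endo)) < rate)
            tumor_seeding[upn] = pd.DataFrame(
                {
                    "clonotype_id": endo["clonotype_id"],
                    "stratum": strata,
                    "observed_in_csf": observed,
                    "seeded": seeded,
                }
            )
            tumor_pool = pd.concat([endo[seeded], tumor_private], ignore_index=True)
            w = np.concatenate(
                [np.full(int(seeded.sum()), 2.0), _background_weights_fixed(cfg, len(tumor_private))]
            )
            sample_t_compartment(SampleKey(upn, cfg.n_cycles, TUMOR), w / w.sum(), tumor_pool, 0.0)

    cells = pd.concat(cell_frames, ignore_index=True)[io_ingest.CELL_COLUMNS]
    contigs = pd.concat(contig_frames, ignore_index=True)
    counts = CountMatrix(
        genes=genes,
        barcodes=count_barcodes,
        matrix=sp.hstack(count_blocks).tocsr(),
    )
    truth = GroundTruth(
        planted_expanders=planted_ids,
        clone_defs=pd.concat(clone_def_frames, ignore_index=True),
        true_car=cells[["barcode", "car_reads"]].assign(
            is_car_positive=cells["car_reads"] >= 3
        )[["barcode", "is_car_positive"]],
        coupled_genes=coupled,
        coupling_slope=cfg.coupling_slope,
        car_pos_schedule_csf=cfg.car_pos_schedule_csf,
        car_pos_fraction_pbmc=cfg.car_pos_fraction_pbmc,
        tumor_seeding=tumor_seeding,
    )
    return TrialData(contigs=contigs, cells=cells, counts=counts, truth=truth, config=cfg)


def _product_weights(cfg: GeneratorConfig) -> np.ndarray:
    w = np.arange(1, cfg.n_product_clones + 1, dtype=float) ** (-cfg.power_exponent)
    return w / w.sum()


def _background_weights_fixed(cfg: GeneratorConfig, n: int) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-cfg.power_exponent)
    return w / w.sum()


# ----------------------------------------------------------------- bundle

def write_bundle(trial: TrialData, directory: str | Path, force: bool = False) -> Path:
    """Write a trial as a 10x-dialect file bundle with a YAML manifest.

    Layout: one contig CSV per sample under ``contigs/``, the cell
    metadata TSV, the MTX triplet under ``counts/``, a summary-level
    ground-truth JSON, and ``manifest.yaml`` tying it together with the
    config and its hash.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise ValidationError(f"output directory {directory} is not empty (use force=True)")
    (directory / "contigs").mkdir(parents=True, exist_ok=True)
    (directory / "counts").mkdir(parents=True, exist_ok=True)

    samples = []
    for (upn, cycle, comp), block in trial.contigs.groupby(["upn", "cycle", "compartment"], sort=True):
        rel = f"contigs/{upn}_c{cycle}_{comp}.csv"
        io_ingest.write_contigs_tenx(block, directory / rel)
        samples.append({"upn": upn, "cycle": int(cycle), "compartment": comp, "contigs": rel})

    io_ingest.write_cell_metadata(trial.cells, directory / "cells.tsv")
    io_ingest.write_counts(
        trial.counts,
        directory / "counts" / "matrix.mtx",
        directory / "counts" / "features.tsv",
        directory / "counts" / "barcodes.tsv",
    )
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(trial.truth.summary_dict(), fh, indent=1, sort_keys=True)

    manifest = {
        "config": trial.config.to_dict(),
        "config_hash": trial.config.hash(),
        "cell_metadata": "cells.tsv",
        "counts": {
            "mtx": "counts/matrix.mtx",
            "features": "counts/features.tsv",
            "barcodes": "counts/barcodes.tsv",
        },
        "ground_truth": "ground_truth.json",
        "samples": samples,
    }
    path = directory / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def read_bundle(directory: str | Path):
    """Read a bundle back through the standard ingest layer.

    Returns ``(contigs, cells, counts, manifest)``; ``counts`` is None if
    the bundle has no count matrix.
    """
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    frames = []
    for s in manifest["samples"]:
        key = SampleKey(s["upn"], int(s["cycle"]), s["compartment"])
        frames.append(io_ingest.read_contigs(directory / s["contigs"], "tenx_csv", sample=key))
    contigs = pd.concat(frames, ignore_index=True)
    cells = io_ingest.read_cell_metadata(directory / manifest["cell_metadata"])
    counts = None
    if manifest.get("counts"):
        c = manifest["counts"]
        counts = io_ingest.read_counts(
            directory / c["mtx"], directory / c["features"], directory / c["barcodes"]
        )
    return contigs, cells, counts, manifest
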