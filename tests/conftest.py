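import pandas as pd
import pytest

from clonodyn.simulate import GeneratorConfig, generate_trial
from clonodyn.types import CSF, PBMC, PRODUCT, TUMOR

#: A deliberately small trial used by integration-style tests: 2 patients,
#: 3 cycles, aggressive tumor seeding so overlap sets are well populated.
SMALL_TRIAL_OVERRIDES = dict(
    seed=42,
    n_patients=2,
    n_cycles=3,
    cells_per_sample={CSF: 250, PBMC: 200, PRODUCT: 120, TUMOR: 150},
    n_background_clones=80,
    n_product_clones=40,
    n_tumor_private_clones=10,
    n_genes=24,
    n_coupled_genes=4,
    car_pos_schedule_csf=(0.4, 0.25, 0.1),
    tumor_seed_rate_expanded=0.5,
    tumor_seed_rate_unexpanded=0.02,
)


def small_config(**overrides) -> GeneratorConfig:
    return GeneratorConfig.from_dict(
        {**GeneratorConfig().to_dict(), **SMALL_TRIAL_OVERRIDES, **overrides}
    )


@pytest.fixture(scope="session")
def small_trial():
    return generate_trial(small_config())


def contig_row(**kw) -> dict:
    base = dict(
        upn="U1", cycle=1, compartment=CSF, barcode="BC1", chain="TRA",
        v_gene="TRAV1", d_gene="None", j_gene="TRAJ1", c_gene="TRAC",
        cdr3_nt="TGTGCAGCC", cdr3_aa="CAA", reads=50, umis=5,
        productive=True, is_cell=True,
    )
    base.update(kw)
    return base


def cell_row(**kw) -> dict:
    base = dict(
        upn="U1", cycle=1, compartment=CSF, barcode="BC1", cell_type="T",
        t_state="CD8_effector", car_reads=0, n_genes=1500, n_counts=4000,
        pct_mito=3.0,
    )
    base.update(kw)
    return base


def contigs_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([contig_row(**r) for r in rows])


def cells_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([cell_row(**r) for r in rows])
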