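import numpy as np
import pytest

import veganome as v


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate synthetic cohort reused by read-only tests."""
    cfg = v.SimulationConfig(
        n_vegan=30, n_nonveg=30, n_metabolites=60, subclass_sizes=[10] * 6,
        frac_nonnull=0.2, n_latent=2, latent_sd=0.5, within_subclass_rho=0.3,
        censor_quantile=0.05, seed=11,
    )
    ds = v.generate_cohort(cfg)
    Y = v.preprocess_pipeline(ds.raw, ds.metadata.table["diet"].to_numpy())
    return ds, Y


@pytest.fixture(scope="session")
def small_fits(small_dataset):
    ds, Y = small_dataset
    design = v.DesignInfo.from_metadata(ds.metadata)
    sv = v.estimate_surrogates(Y, design, n_sv="auto", seed=11)
    fits = v.fit_metabolite_models(Y, design, sv=sv if sv.k else None)
    return ds, Y, design, fits


def null_cohort(seed, n_vegan=47, n_nonveg=46, p=300, rho=0.0, n_latent=0,
                latent_sd=0.3, censor=0.0, **kw):
    """Global-null cohort helper shared by calibration tests."""
    cfg = v.SimulationConfig(
        n_vegan=n_vegan, n_nonveg=n_nonveg, n_metabolites=p,
        subclass_sizes=[10] * (p // 10), frac_nonnull=0.0, n_latent=n_latent,
        latent_sd=latent_sd, within_subclass_rho=rho, censor_quantile=censor,
        seed=seed, **kw,
    )
    ds = v.generate_cohort(cfg)
    Y = v.preprocess_pipeline(ds.raw, ds.metadata.table["diet"].to_numpy())
    return ds, Y
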