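import io

import numpy as np
import pandas as pd
import pytest

from saltscreen import simulate
from saltscreen.ojip import JipMarks


@pytest.fixture
def toy_marks():
    """Marks whose JIP parameters are all round numbers by hand arithmetic."""
    return JipMarks(F0=500.0, F300=900.0, FJ=1500.0, FM=2500.0)


@pytest.fixture
def transient_csv():
    """Long-format table: two interleaved samples plus one duplicate time."""
    rows = ["sample_id,time_s,fluorescence"]
    times = np.logspace(-5, 0, 40)
    for s, scale in (("s1", 1.0), ("s2", 2.0)):
        for t in times:
            f = scale * (500 + 2000 * (1 - np.exp(-t / 1e-3)))
            rows.append(f"{s},{t},{f}")
    rows += ["s3,1e-5,100", "s3,2e-3,300", "s3,1,500"]
    return "\n".join(rows)


@pytest.fixture
def small_panel():
    """Deterministic low-noise panel, 6 varieties, planted marker RF near 2.3."""
    return simulate.simulate_panel(simulate.PanelSimConfig(n_varieties=6, seed=11))


@pytest.fixture
def fixed_genotypes():
    """Two populations fixed for different alleles at every locus."""
    inds = [f"i{k}" for k in range(8)]
    calls = pd.DataFrame(
        {f"L{j}": ["a/a"] * 4 + ["b/b"] * 4 for j in range(3)}, index=inds
    )
    pops = {ind: ("p1" if k < 4 else "p2") for k, ind in enumerate(inds)}
    from saltscreen.diversity import GenotypeMatrix

    return GenotypeMatrix(calls), pops
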