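"""Shared fixtures: small hand-built structures and one session-scoped
synthetic benchmark set that the statistical tests reuse."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import loopbench as lb
from loopbench.pipeline import RunConfig, run_benchmark
from loopbench.structure_io import Atom, Residue, Structure
from loopbench.synthetic_data import SyntheticSpec, generate_benchmark_set

BENCH_SEED = 11
BENCH_N_PROTEINS = 60


def make_residue(seq_num: int, coords_by_name: dict[str, tuple], aa="A",
                 name="ALA", bfactor=0.0) -> Residue:
    return Residue(
        aa=aa, seq_id=str(seq_num), name=name,
        atoms=[Atom(name=n, element=n[0], coords=np.asarray(c, dtype=float),
                    bfactor=bfactor)
               for n, c in coords_by_name.items()],
    )


@pytest.fixture
def two_residue_structure() -> Structure:
    """Two poly-Ala residues with 4 backbone atoms each (8 ATOM records)."""
    st = Structure(id="mini", source="experimental")
    st.chains["A"] = [
        make_residue(1, {"N": (0, 0, 0), "CA": (1.458, 0, 0),
                         "C": (2.0, 1.4, 0), "O": (1.5, 2.4, 0.4)}),
        make_residue(2, {"N": (3.3, 1.5, 0), "CA": (4.2, 2.6, 0.2),
                         "C": (5.6, 2.1, 0.4), "O": (6.5, 2.9, 0.6)}),
    ]
    return st


@pytest.fixture(scope="session")
def helix12() -> Structure:
    return lb.make_ideal_segment("alpha_helix", 12)


@pytest.fixture(scope="session")
def hairpin_sheet() -> Structure:
    return lb.make_ideal_sheet(8, "antiparallel")


@pytest.fixture(scope="session")
def parallel_sheet() -> Structure:
    return lb.make_ideal_sheet(8, "parallel")


@pytest.fixture(scope="session")
def extended_chain() -> Structure:
    from loopbench.synthetic_data import build_backbone, _structure_from
    coords = build_backbone([(180.0, 180.0)] * 10)
    return _structure_from(coords, "A" * 10, "extended", "experimental")


@pytest.fixture(scope="session")
def bench_spec() -> SyntheticSpec:
    return SyntheticSpec(n_proteins=BENCH_N_PROTEINS, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def bench_dir(tmp_path_factory, bench_spec):
    out = tmp_path_factory.mktemp("bench")
    generate_benchmark_set(bench_spec, out)
    return out


@pytest.fixture(scope="session")
def bench_manifest(bench_dir) -> pd.DataFrame:
    return pd.read_csv(bench_dir / "manifest.tsv", sep="\t")


@pytest.fixture(scope="session")
def bench_truth(bench_dir) -> pd.DataFrame:
    return pd.read_csv(bench_dir / "truth.tsv", sep="\t")


@pytest.fixture(scope="session")
def bench_result(bench_manifest):
    return run_benchmark(
        list(bench_manifest.itertuples(index=False, name=None)), RunConfig())
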