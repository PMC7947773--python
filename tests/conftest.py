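"""Shared fixtures: small synthetic cohorts and hand-built trees."""

import numpy as np
import pandas as pd
import pytest

from lineage_clockwork import CohortConfig, render_sequencing, simulate_cohort
from lineage_clockwork.trees import Node


@pytest.fixture(scope="session")
def small_cfg():
    """A fast 3-haplogroup cohort for plumbing tests."""
    return CohortConfig(
        n_haplogroups=3,
        samples_per_haplogroup=5,
        master_seed=42,
        l_y=400_000,
        l_x=400_000,
        window_size=4_000,
        n_sites=12_000,
        base_somatic_burden=25.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    truth = simulate_cohort(small_cfg)
    rendered = render_sequencing(truth, small_cfg)
    return small_cfg, truth, rendered


@pytest.fixture
def balanced_tree():
    """((A:1,B:1):1,(C:1,D:1):1) — ultrametric, depth 2."""

    def build(bl_a=1.0):
        root = Node()
        ab, cd = Node(length=1.0), Node(length=1.0)
        ab.add_child(Node("A", bl_a))
        ab.add_child(Node("B", 1.0))
        cd.add_child(Node("C", 1.0))
        cd.add_child(Node("D", 1.0))
        root.add_child(ab)
        root.add_child(cd)
        return root

    return build


def make_calls(rows):
    """Helper: variant-call frame from (sample, chrom, pos, ref, alt, rr, ar) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "ref_reads", "alt_reads"],
    )
    df["depth"] = df["ref_reads"] + df["alt_reads"]
    return df
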