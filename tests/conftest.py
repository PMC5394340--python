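"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from mapanchor.haplo import apply_chimera_splits, consensus_matrix, detect_chimeras
from mapanchor.linkmap import build_binmap
from mapanchor.simpop import PRESETS, simulate


@pytest.fixture(scope="session")
def toy_sim():
    """Toy-preset simulation with planted superscaffold misjoins."""
    return simulate(PRESETS["toy"], superscaffold_misjoin_fraction=0.1)


@pytest.fixture(scope="session")
def lettuce_run():
    """One lettuce-like run taken through chimera splitting and mapping."""
    sim = simulate(PRESETS["lettuce-like"], superscaffold_misjoin_fraction=0.04)
    reports = detect_chimeras(sim.table)
    table, split_map, lengths, _ = apply_chimera_splits(
        sim.table, reports, sim.truth.scaffold_lengths()
    )
    hap = consensus_matrix(table)
    bin_map = build_binmap(hap, lengths)
    return {
        "sim": sim,
        "reports": reports,
        "table": table,
        "split_map": split_map,
        "lengths": lengths,
        "hap": hap,
        "bin_map": bin_map,
    }


def lg_directions(bin_map, sim):
    """Sign of each LG's bin order relative to true chromosome coordinates.

    An LG's internal direction is arbitrary; orientation calls are correct
    up to this per-LG flip (a real map fixes direction against an external
    reference).
    """
    import numpy as np

    truth = sim.truth.scaffolds.set_index("scaffold_id")
    signs = {}
    for lg, bins in bin_map.lgs.items():
        pos, idx = [], []
        for b in bins:
            for s in b.members:
                base = s.split("_p")[0]
                pos.append(float(truth.loc[base, "start"]))
                idx.append(b.bin_id)
        signs[lg] = 1.0 if np.corrcoef(pos, idx)[0, 1] >= 0 else -1.0
    return signs


def true_chromosome_labels(sim, scaffold_ids):
    """Truth chromosome per (possibly split) scaffold id.

    The tail part (_p2) of a split chimera genuinely belongs to the donor
    chromosome; every other id inherits its base scaffold's chromosome.
    """
    truth_chrom = dict(
        zip(sim.truth.scaffolds["scaffold_id"], sim.truth.scaffolds["chrom"])
    )
    donor = dict(
        zip(sim.truth.chimeras["scaffold_id"], sim.truth.chimeras["donor_chrom"])
    )
    labels = []
    for sid in scaffold_ids:
        if "_p" in sid:
            base, part = sid.rsplit("_p", 1)
            if base in donor and part == "2":
                labels.append(int(donor[base]))
                continue
            labels.append(int(truth_chrom[base]))
        else:
            labels.append(int(truth_chrom[sid]))
    return labels
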