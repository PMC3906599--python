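import numpy as np
import pytest

from longgei.data import (
    PedigreeMember,
    PhenotypeRecord,
    build_dataset,
)


def make_members(fam="F1", n_kids=2):
    m = [
        PedigreeMember(fam, f"{fam}_P1", None, None, "male"),
        PedigreeMember(fam, f"{fam}_P2", None, None, "female"),
    ]
    for k in range(n_kids):
        m.append(
            PedigreeMember(fam, f"{fam}_C{k + 1}", f"{fam}_P1", f"{fam}_P2", "male")
        )
    return m


def make_record(member, visit, hdlc=50.0, alcohol=2.0, **kw):
    defaults = dict(age=50.0, bmi=27.0, med_use=0.0)
    defaults.update(kw)
    return PhenotypeRecord(
        family_id=member.family_id,
        individual_id=member.individual_id,
        visit=visit,
        sex=member.sex,
        hdlc=hdlc,
        alcohol=alcohol,
        **defaults,
    )


@pytest.fixture
def two_family_dataset():
    """2 families x 2 members x 2 visits, fully observed, deterministic values."""
    rng = np.random.default_rng(7)
    members, records = [], []
    for fam in ("F1", "F2"):
        ms = make_members(fam, n_kids=0)
        members.extend(ms)
        for m in ms:
            for v in (1, 2):
                records.append(
                    make_record(
                        m, v,
                        hdlc=float(50 + rng.normal()),
                        alcohol=float(rng.uniform(0, 5)),
                        age=float(rng.uniform(40, 70)),
                        bmi=float(rng.uniform(22, 33)),
                        med_use=float(rng.integers(0, 2)),
                    )
                )
    return build_dataset(members, records, visit_grid=(1, 2))


@pytest.fixture
def small_sim():
    """A modest simulated dataset reused by several test modules."""
    from longgei.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(
        n_families=60, n_snps=4, snp_effects={0: (3.0, 0.0), 1: (0.0, 0.6)}
    )
    return simulate_dataset(cfg, 11)
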