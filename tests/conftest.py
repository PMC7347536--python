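import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tmbkit.model import PanelOfNormals, SampleCallset, VariantCall

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_call(
    chrom="chr1",
    pos=100,
    ref="C",
    alt="T",
    total_depth=100,
    alt_depth=40,
    alt_fwd=None,
    mq_pass_fraction=0.95,
    variant_class="snv",
    splice_offset=None,
    population_maf=None,
    in_dbsnp=False,
    in_cosmic=False,
    truth_label=None,
):
    """VariantCall factory with consistent derived fields."""
    if alt_fwd is None:
        alt_fwd = alt_depth // 2
    return VariantCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        total_depth=total_depth,
        alt_depth=alt_depth,
        vaf=alt_depth / total_depth if total_depth else 0.0,
        alt_fwd=alt_fwd,
        alt_rev=alt_depth - alt_fwd,
        mq_pass_fraction=mq_pass_fraction,
        variant_class=variant_class,
        splice_offset=splice_offset,
        population_maf=population_maf,
        in_dbsnp=in_dbsnp,
        in_cosmic=in_cosmic,
        truth_label=truth_label,
    )


def make_callset(calls, sample_id="T1", assay_id="exome", mode="tumor_only", **kw):
    return SampleCallset(
        sample_id=sample_id, assay_id=assay_id, mode=mode, calls=list(calls), **kw
    )


@pytest.fixture
def empty_pon():
    return PanelOfNormals(entries={}, n_normals=0)


def random_callset(rng: np.random.Generator, n_calls: int, n_normals: int = 5):
    """Random but invariant-respecting callset plus a random panel of normals
    covering a subset of its calls (for equivalence/property testing)."""
    classes = np.array(
        ["snv", "indel", "frameshift", "start_stop", "splice", "synonymous", "other"]
    )
    positions = rng.choice(10**6, size=n_calls, replace=False) + 1
    calls = []
    for pos in positions:
        depth = int(rng.integers(1, 500))
        alt = int(rng.integers(1, depth + 1))
        fwd = int(rng.integers(0, alt + 1))
        vclass = str(rng.choice(classes))
        calls.append(
            VariantCall(
                chrom="chr1",
                pos=int(pos),
                ref="C",
                alt="T",
                total_depth=depth,
                alt_depth=alt,
                vaf=alt / depth,
                alt_fwd=fwd,
                alt_rev=alt - fwd,
                mq_pass_fraction=float(rng.uniform(0.5, 1.0)),
                variant_class=vclass,
                splice_offset=(
                    int(rng.integers(-5, 6)) if vclass == "splice" else None
                ),
                population_maf=(
                    float(10 ** rng.uniform(-6, -0.31))
                    if rng.random() < 0.5
                    else None
                ),
                in_dbsnp=bool(rng.random() < 0.4),
                in_cosmic=bool(rng.random() < 0.2),
            )
        )
    entries = {}
    for call in calls:
        if rng.random() < 0.4:
            k = int(rng.integers(1, 4))
            entries[call.key] = [
                (f"n{j}", float(rng.uniform(0.01, 0.6))) for j in range(k)
            ]
    pon = PanelOfNormals(entries=entries, n_normals=n_normals)
    return make_callset(calls), pon
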