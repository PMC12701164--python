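import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctviz.chunking import (
    combine_chunks,
    compute_chunk_size,
    compute_total_chunks,
    make_chunk_plan,
    split_volume,
    stream_chunks,
)
from ctviz.errors import BudgetError, ValidationError
from ctviz.resources import MIB, ResourceProfile, upload_budget
from ctviz.volume_io import Volume


class TestUploadBudget:
    def test_fraction_of_heap(self):
        profile = ResourceProfile(heap_limit_bytes=4095.75 * MIB)
        assert upload_budget(profile) == pytest.approx(3071.8125 * MIB)

    def test_fallback_when_heap_unknown(self):
        profile = ResourceProfile(heap_limit_bytes=None)
        assert upload_budget(profile) == 2048 * MIB

    def test_identity_fraction(self):
        profile = ResourceProfile(heap_limit_bytes=100.0, upload_fraction=1.0)
        assert upload_budget(profile) == 100.0

    @given(
        heap=st.floats(min_value=1.0, max_value=1e12),
        bump=st.floats(min_value=0.0, max_value=1e12),
        frac=st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_heap_and_fraction(self, heap, bump, frac):
        lo = upload_budget(ResourceProfile(heap_limit_bytes=heap, upload_fraction=frac))
        hi = upload_budget(ResourceProfile(heap_limit_bytes=heap + bump, upload_fraction=frac))
        assert hi >= lo
        hi_frac = upload_budget(
            ResourceProfile(heap_limit_bytes=heap, upload_fraction=min(1.0, frac * 1.5))
        )
        assert hi_frac >= lo


class TestChunkSize:
    def test_reference_configuration(self):
        profile = ResourceProfile(
            max_3d_texture_size=2048, chunk_factor=0.25, heap_limit_bytes=4095.75 * MIB
        )
        assert compute_chunk_size(profile) == 512

    def test_texture_term(self):
        profile = ResourceProfile(max_3d_texture_size=8, chunk_factor=0.5,
                                  heap_limit_bytes=1e15)
        assert compute_chunk_size(profile) == 4

    @given(
        tex=st.integers(min_value=2, max_value=4096),
        factor=st.floats(min_value=0.05, max_value=1.0),
        budget=st.floats(min_value=4.0, max_value=1e10),
    )
    @settings(max_examples=80, deadline=None)
    def test_min_of_both_operands(self, tex, factor, budget):
        # brute-force oracle over both operands of the min
        profile = ResourceProfile(
            max_3d_texture_size=tex, chunk_factor=factor,
            heap_limit_bytes=budget, upload_fraction=1.0,
        )
        expected = min(math.floor(tex * factor), math.floor(budget / 2))
        if expected < 1:
            with pytest.raises(BudgetError):
                compute_chunk_size(profile)
        else:
            assert compute_chunk_size(profile) == expected

    def test_monotone_in_texture_size(self):
        sizes = [
            compute_chunk_size(
                ResourceProfile(max_3d_texture_size=t, heap_limit_bytes=1e12)
            )
            for t in (64, 128, 512, 2048)
        ]
        assert sizes == sorted(sizes)

    def test_budget_in_slices_conversion(self):
        profile = ResourceProfile(max_3d_texture_size=2048, chunk_factor=0.25,
                                  heap_limit_bytes=4095.75 * MIB)
        bytes_per_slice = 512 * 512 * 2
        out = compute_chunk_size(profile, bytes_per_slice=bytes_per_slice,
                                 budget_in_slices=True)
        expected = min(512, math.floor(0.75 * 4095.75 * MIB / 2 / bytes_per_slice))
        assert out == expected


class TestTotalChunks:
    @pytest.mark.parametrize(
        "depth,size,expected", [(1639, 512, 4), (2239, 512, 5), (2041, 512, 4), (512, 512, 1)]
    )
    def test_reference_depths(self, depth, size, expected):
        assert compute_total_chunks(depth, size) == expected

    @given(depth=st.integers(1, 64), size=st.integers(1, 64))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_range_enumeration(self, depth, size):
        # oracle: count slabs by explicit enumeration
        count = 0
        z = 0
        while z < depth:
            z = min(z + size, depth)
            count += 1
        assert compute_total_chunks(depth, size) == count
        plan = make_chunk_plan(depth, size)
        assert plan.total_chunks == count
        assert sum(z1 - z0 for z0, z1 in plan.ranges) == depth


class TestSplitCombine:
    def test_depth10_chunk4_tiling(self):
        plan = make_chunk_plan(10, 4)
        assert [z1 - z0 for z0, z1 in plan.ranges] == [4, 4, 2]

    def test_last_chunk_depth_1639(self):
        plan = make_chunk_plan(1639, 512)
        assert plan.ranges[-1][1] - plan.ranges[-1][0] == 1639 - 3 * 512

    def test_chunks_equal_parent_slabs(self, random_volume):
        plan = make_chunk_plan(random_volume.dims[2], 3)
        for c in split_volume(random_volume, plan):
            np.testing.assert_array_equal(
                c.volume.data, random_volume.data[:, :, c.z_start : c.z_end]
            )
            assert c.volume.origin[2] == pytest.approx(
                random_volume.origin[2] + c.z_start * random_volume.spacing[2]
            )

    @given(
        depth=st.integers(1, 40),
        size=st.integers(1, 40),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=40, deadline=None)
    def test_combine_split_identity(self, depth, size, seed):
        rng = np.random.default_rng(seed)
        vol = Volume(rng.integers(-500, 500, size=(4, 5, depth), dtype=np.int16),
                     spacing=(0.9, 1.0, 0.625))
        plan = make_chunk_plan(depth, size)
        back = combine_chunks(split_volume(vol, plan))
        np.testing.assert_array_equal(back.data, vol.data)
        assert back.spacing == vol.spacing and back.origin == vol.origin

    def test_single_chunk_identity(self, random_volume):
        plan = make_chunk_plan(random_volume.dims[2], random_volume.dims[2])
        back = combine_chunks(split_volume(random_volume, plan))
        np.testing.assert_array_equal(back.data, random_volume.data)

    def test_shuffled_chunks_rejected(self, random_volume):
        chunks = split_volume(random_volume, make_chunk_plan(random_volume.dims[2], 3))
        with pytest.raises(ValidationError):
            combine_chunks(chunks[::-1])


class TestStreaming:
    def test_yields_monotone_accounting(self, random_volume):
        plan = make_chunk_plan(random_volume.dims[2], 3)
        pairs = list(stream_chunks(random_volume, plan, budget=1e9))
        assert len(pairs) == plan.total_chunks
        used = [u for _, u in pairs]
        assert all(b > a for a, b in zip(used, used[1:]))

    def test_final_used_bytes_is_total_payload(self, random_volume):
        w, h, d = random_volume.dims
        plan = make_chunk_plan(d, 4)
        *_, (_, used) = stream_chunks(random_volume, plan, budget=1e9)
        assert used == w * h * d * random_volume.data.dtype.itemsize

    def test_budget_smaller_than_one_chunk(self, random_volume):
        plan = make_chunk_plan(random_volume.dims[2], 4)
        with pytest.raises(BudgetError):
            list(stream_chunks(random_volume, plan, budget=16))
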