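"""Group activity descriptors (GADs).

A group conversation is represented by the concatenation of its four
participants' FADs.  Because the participant order carries no meaning, the
four FADs are concatenated in all 4! = 24 orderings, each yielding one
training instance with the group's label.  Within one instance the layout is
participant-major, segment-minor: for each participant slot (in permutation
order) the per-part FADs follow in temporal order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .descriptors import (
    STATS_PER_CHANNEL,
    FadVector,
    SegmentSpec,
    compute_fads,
)
from .errors import LayoutError, ProtocolError
from .io import FeatureSetSpec, GroupRecord

N_PARTICIPANTS = 4
#: All orderings of the four participant slots, lexicographic.
PERMUTATIONS: tuple[tuple[int, ...], ...] = tuple(permutations(range(N_PARTICIPANTS)))
N_PERMUTATIONS = len(PERMUTATIONS)  # 24


@dataclass
class GadInstance:
    session_id: str
    group_id: str
    permutation: tuple[int, ...]
    values: np.ndarray
    label: int


@dataclass
class GadLayout:
    """Dimension bookkeeping of a GAD: which base channel each column holds."""

    feature_set: str
    segment: SegmentSpec
    channel_names: tuple[str, ...]

    @property
    def block_length(self) -> int:
        """Length of one participant block (all parts)."""
        return self.segment.n_parts * len(self.channel_names) * STATS_PER_CHANNEL

    @property
    def dimension(self) -> int:
        return N_PARTICIPANTS * self.block_length

    def channel_of_dim(self) -> np.ndarray:
        """Registry-channel index of every GAD dimension (for importance
        aggregation): participant-major, part-, channel-, variant-, stat-minor."""
        per_channel = np.repeat(np.arange(len(self.channel_names)), STATS_PER_CHANNEL)
        per_part = np.tile(per_channel, self.segment.n_parts)
        return np.tile(per_part, N_PARTICIPANTS)


def gad_dimension(spec: FeatureSetSpec, segment: SegmentSpec = SegmentSpec()) -> int:
    """Instance length: 4 participants x parts x channels x 48 statistics."""
    return N_PARTICIPANTS * segment.n_parts * len(spec) * STATS_PER_CHANNEL


def build_gads(group: GroupRecord, fads: list[list[FadVector]]) -> list[GadInstance]:
    """All 24 permutation instances of one group.

    ``fads`` holds, per participant, the list of per-part FADs in temporal
    order.  Every instance carries the group's label.
    """
    if len(fads) != N_PARTICIPANTS:
        raise ProtocolError(f"expected FADs for 4 participants, got {len(fads)}")
    blocks = [np.concatenate([f.values for f in per_part]) for per_part in fads]
    lengths = {b.shape[0] for b in blocks}
    if len(lengths) != 1:
        raise LayoutError(f"participant FAD blocks differ in length: {sorted(lengths)}")
    return [
        GadInstance(
            session_id=group.session_id,
            group_id=group.group_id,
            permutation=perm,
            values=np.concatenate([blocks[i] for i in perm]),
            label=group.label,
        )
        for perm in PERMUTATIONS
    ]


def gads_for_group(
    group: GroupRecord,
    spec: FeatureSetSpec,
    segment: SegmentSpec = SegmentSpec(),
) -> list[GadInstance]:
    """Descriptor extraction + permutation augmentation for one group."""
    fads = [compute_fads(p, spec, segment) for p in group.participants]
    return build_gads(group, fads)
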