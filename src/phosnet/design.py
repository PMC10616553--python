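"""TMT study designs: plexes, channels, samples and conditions.

A TMT10 plex carries up to ten isobarically labeled samples in one MS run.
The default design mirrors a common multi-cell-line layout: one plex per
cell line, eight biological samples per plex (four drug-treated, four
vehicle) plus two reference-pool channels, so that log ratios against the
in-plex reference are comparable across plexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

TREATED = "treated"
VEHICLE = "vehicle"
REFERENCE = "reference"


@dataclass(frozen=True)
class Channel:
    """One reporter-ion channel of a plex."""

    index: int  # 1-based channel number within the plex
    role: str  # treated | vehicle | reference
    sample_id: str | None = None  # None for reference channels
    replicate: int | None = None


@dataclass(frozen=True)
class Plex:
    plex_id: str
    cell_line: str
    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        n_ref = sum(c.role == REFERENCE for c in self.channels)
        if n_ref != 2:
            raise ValueError(
                f"plex {self.plex_id}: expected exactly 2 reference channels, got {n_ref}"
            )

    @property
    def sample_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.role != REFERENCE)

    @property
    def reference_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.role == REFERENCE)


@dataclass(frozen=True)
class StudyDesign:
    """A set of TMT plexes with their channel-to-sample maps."""

    plexes: tuple[Plex, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.plexes) < 1:
            raise ValueError("a study design needs at least one plex")

    @property
    def samples(self) -> list[Channel]:
        return [c for p in self.plexes for c in p.sample_channels]

    @property
    def sample_ids(self) -> list[str]:
        return [c.sample_id for c in self.samples]

    def plex_of(self, sample_id: str) -> str:
        for p in self.plexes:
            if any(c.sample_id == sample_id for c in p.sample_channels):
                return p.plex_id
        raise KeyError(sample_id)

    def cell_line_of(self, sample_id: str) -> str:
        for p in self.plexes:
            if any(c.sample_id == sample_id for c in p.sample_channels):
                return p.cell_line
        raise KeyError(sample_id)

    def condition_of(self, sample_id: str) -> str:
        for c in self.samples:
            if c.sample_id == sample_id:
                return c.role
        raise KeyError(sample_id)

    @property
    def cell_lines(self) -> list[str]:
        seen: list[str] = []
        for p in self.plexes:
            if p.cell_line not in seen:
                seen.append(p.cell_line)
        return seen


def make_plex(plex_id: str, cell_line: str, n_replicates: int = 4) -> Plex:
    """Build a TMT10 plex: treated replicates, vehicle replicates, 2 refs."""
    channels: list[Channel] = []
    idx = 1
    for role in (TREATED, VEHICLE):
        for rep in range(1, n_replicates + 1):
            channels.append(
                Channel(idx, role, sample_id=f"{cell_line}_{role}_{rep}", replicate=rep)
            )
            idx += 1
    channels.append(Channel(idx, REFERENCE))
    channels.append(Channel(idx + 1, REFERENCE))
    return Plex(plex_id, cell_line, tuple(channels))


def default_design(cell_lines: tuple[str, ...] = ("CL1", "CL2", "CL3")) -> StudyDesign:
    """Three cell lines x (4 treated + 4 vehicle), one TMT10 plex each: 24 samples."""
    return StudyDesign(
        tuple(make_plex(f"plex{i + 1}", cl) for i, cl in enumerate(cell_lines))
    )
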