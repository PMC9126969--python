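"""Multi-scale convolution kernel decomposition.

A single fixed-scale ``h x w`` kernel is split into an ordered set of four
smaller kernels by halving each dimension with floor/ceil rounding:

    h x w  ->  [ (⌊h/2⌋, ⌊w/2⌋), (⌊h/2⌋, ⌈w/2⌉), (⌈h/2⌉, ⌊w/2⌋), (⌈h/2⌉, ⌈w/2⌉) ]

so a 5x5 kernel decomposes into [2x2, 2x3, 3x2, 3x3].  The four shapes are
assigned one per convolution layer in the multi-scale CNN, or one per
backbone branch in the ensemble model.  For even dimensions the floor and
ceil halves coincide and the resulting duplicates are kept, so the set
always has exactly four members and the four-branch architecture is
preserved.

The rule is only demonstrated at 5x5 in the originating method; its
extension to arbitrary ``h, w >= 2`` (the minimal floor/ceil
generalization) is this package's own definition.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class KernelShape:
    """A convolution kernel extent in pixels (height, width)."""

    h: int
    w: int

    def __post_init__(self) -> None:
        if self.h < 1 or self.w < 1:
            raise ValueError(f"kernel dimensions must be >= 1, got {self.h}x{self.w}")

    def as_tuple(self) -> tuple[int, int]:
        return (self.h, self.w)

    def __str__(self) -> str:  # "2x3" style, used in model names
        return f"{self.h}x{self.w}"


@dataclass(frozen=True)
class KernelSet:
    """The ordered decomposition set [small×small, small×large, large×small, large×large]."""

    kernels: tuple[KernelShape, KernelShape, KernelShape, KernelShape]

    def __post_init__(self) -> None:
        if len(self.kernels) != 4:
            raise ValueError(f"a kernel set has exactly 4 members, got {len(self.kernels)}")

    def __iter__(self):
        return iter(self.kernels)

    def __getitem__(self, i: int) -> KernelShape:
        return self.kernels[i]

    def as_tuples(self) -> list[tuple[int, int]]:
        return [k.as_tuple() for k in self.kernels]


def decompose_kernel(shape: KernelShape | tuple[int, int]) -> KernelSet:
    """Decompose one kernel shape into the ordered four-member multi-scale set.

    Parameters
    ----------
    shape
        Base kernel, both dimensions >= 2 (a 1x1 kernel has nothing to split).

    Returns
    -------
    KernelSet
        ``[(a_h,a_w), (a_h,b_w), (b_h,a_w), (b_h,b_w)]`` with
        ``a = floor(dim/2)`` and ``b = ceil(dim/2)``; for odd dimensions the
        two halves sum back to the original extent.
    """
    if not isinstance(shape, KernelShape):
        shape = KernelShape(*shape)
    if shape.h < 2 or shape.w < 2:
        raise ValueError(
            f"cannot decompose a {shape} kernel: both dimensions must be >= 2"
        )
    a_h, b_h = shape.h // 2, shape.h - shape.h // 2
    a_w, b_w = shape.w // 2, shape.w - shape.w // 2
    return KernelSet(
        (
            KernelShape(a_h, a_w),
            KernelShape(a_h, b_w),
            KernelShape(b_h, a_w),
            KernelShape(b_h, b_w),
        )
    )
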