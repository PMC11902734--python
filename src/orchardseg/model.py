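"""Assembly of the ghost-attention segmentation network.

Backbone: two stride-2 convolutions, then alternating C2f stages and
stride-2 ghost bottlenecks (in place of the usual dense downsampling
convolutions), closed by SPPF.  Neck: top-down upsample/concat path with
C2f fusion, a global attention module after each of the two finest fused
maps, then a bottom-up path re-concatenating the mid and coarse levels.
Head: anchor-free, decoupled per-scale branches for box-distribution
logits (4*reg_max bins), class logits and mask coefficients, plus a mask
prototype head at stride-8 resolution.

Nominal widths follow the full-scale layer table (64..1024 channels,
iterations 3/6/6/3 in the backbone); ``width_multiple``/``depth_multiple``
scale them, and the "tiny" preset (0.25/0.34) exists solely to make
desk-scale CPU training practical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .blocks import (C2f, Conv, GAM, GhostBottleneck, Module, SPPF)


@dataclass
class ModelSpec:
    num_classes: int = 2
    input_size: int = 640
    width_multiple: float = 1.0
    depth_multiple: float = 1.0
    reg_max: int = 16
    n_prototypes: int = 32
    strides: tuple[int, int, int] = (8, 16, 32)
    se_mode: str = "stride2"  # SE active in stride-2 ghost bottlenecks
    se_reduction: int = 4
    gam_reduction: int = 4
    spatial_kernel: int = 7
    ghost_ratio: int = 2

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.se_mode not in ("stride2", "all", "none"):
            raise ValueError("se_mode must be stride2|all|none")

    def channels(self, c: int) -> int:
        """Width-scaled channel count: >= 8 and divisible by 4."""
        return max(8, int(round(c * self.width_multiple / 4)) * 4)

    def depth(self, n: int) -> int:
        return max(1, int(round(n * self.depth_multiple)))

    @classmethod
    def tiny(cls, input_size: int = 320, **kw) -> "ModelSpec":
        """Quarter-width preset for CPU-scale experiments (not the nominal
        full-scale configuration)."""
        return cls(width_multiple=0.25, depth_multiple=0.34,
                   input_size=input_size, **kw)


@dataclass
class RawPredictions:
    """Per-scale raw head outputs plus shared mask prototypes."""

    box: list  # per scale: (B, 4*reg_max, h, w)
    cls: list  # per scale: (B, num_classes, h, w)
    coef: list  # per scale: (B, n_prototypes, h, w)
    protos: object  # (B, n_prototypes, S/8, S/8)
    strides: tuple = (8, 16, 32)


class _HeadBranch(Module):
    def __init__(self, c_in: int, hidden: int, c_out: int, out_bias: float,
                 rng: np.random.Generator):
        self.cv1 = Conv(c_in, hidden, 3, rng=rng)
        self.cv2 = Conv(hidden, hidden, 3, rng=rng)
        self.out = Conv(hidden, c_out, 1, act=None, bn=False, bias=True, rng=rng)
        self.out.bias.data[:] = out_bias

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return self.out(self.cv2(self.cv1(x, training), training), training)


class SegmentationHead(Module):
    """Decoupled box / class / mask-coefficient branches per scale, and a
    prototype head reading the stride-8 feature map."""

    def __init__(self, spec: ModelSpec, in_channels: tuple[int, int, int],
                 rng: np.random.Generator):
        self.spec = spec
        nc, nm, rm = spec.num_classes, spec.n_prototypes, spec.reg_max
        self.box_branches, self.cls_branches, self.coef_branches = [], [], []
        for c in in_channels:
            h = max(16, c // 4)
            box = _HeadBranch(c, h, 4 * rm, 0.0, rng)
            # decaying per-bin bias: the initial side-distance expectation
            # is ~1.5 bins instead of the uniform distribution's rm/2, so
            # untrained boxes are compact and thin objects (stems) start
            # with workable IoU in the aligned assignment
            box.out.bias.data[:] = np.tile(-0.5 * np.arange(rm, dtype=np.float32), 4)
            self.box_branches.append(box)
            # class logits start strongly negative so an untrained model is
            # not saturated with false positives
            self.cls_branches.append(_HeadBranch(c, max(h, nc), nc, -4.6, rng))
            self.coef_branches.append(_HeadBranch(c, h, nm, 0.0, rng))
        cp = max(nm, in_channels[0] // 2)
        self.proto1 = Conv(in_channels[0], cp, 3, rng=rng)
        self.proto2 = Conv(cp, cp, 3, rng=rng)
        self.proto3 = Conv(cp, nm, 1, rng=rng)

    def forward_multi(self, feats: list[Tensor], training: bool = False) -> RawPredictions:
        box = [b(f, training) for b, f in zip(self.box_branches, feats)]
        cls = [b(f, training) for b, f in zip(self.cls_branches, feats)]
        coef = [b(f, training) for b, f in zip(self.coef_branches, feats)]
        protos = self.proto3(self.proto2(self.proto1(feats[0], training), training),
                             training)
        return RawPredictions(box, cls, coef, protos, self.spec.strides)


class SegmentationModel(Module):
    """The full backbone + neck + head graph.

    ``ghost=False`` builds the ablation variant in which the three ghost
    bottlenecks are replaced by dense stride-2 3x3 convolutions with the
    same channel map (used for the parameter-efficiency comparison).
    """

    def __init__(self, spec: ModelSpec | None = None, seed: int = 0,
                 ghost: bool = True):
        spec = spec or ModelSpec()
        self.spec = spec
        self.ghost = ghost
        rng = np.random.default_rng(seed)
        ch = spec.channels
        c64, c128, c256, c512, c1024 = (ch(64), ch(128), ch(256), ch(512), ch(1024))
        se = {"stride2": True, "all": True, "none": False}[spec.se_mode]

        def down(c1, c2):
            if ghost:
                return GhostBottleneck(c1, c2, k=3, s=2, use_se=se,
                                       r=spec.ghost_ratio,
                                       se_reduction=spec.se_reduction, rng=rng)
            return Conv(c1, c2, 3, 2, rng=rng)

        # backbone (layer table order)
        self.conv1 = Conv(3, c64, 3, 2, rng=rng)
        self.conv2 = Conv(c64, c128, 3, 2, rng=rng)
        self.c2f1 = C2f(c128, c128, spec.depth(3), shortcut=True, rng=rng)
        self.gb1 = down(c128, c256)
        self.c2f2 = C2f(c256, c256, spec.depth(6), shortcut=True, rng=rng)
        self.gb2 = down(c256, c512)
        self.c2f3 = C2f(c512, c512, spec.depth(6), shortcut=True, rng=rng)
        self.gb3 = down(c512, c1024)
        self.c2f4 = C2f(c1024, c1024, spec.depth(3), shortcut=True, rng=rng)
        self.sppf = SPPF(c1024, c1024, 5, rng=rng)
        # neck
        self.c2f5 = C2f(c1024 + c512, c512, spec.depth(3), rng=rng)
        self.c2f6 = C2f(c512 + c256, c256, spec.depth(3), rng=rng)
        self.gam1 = GAM(c256, spec.gam_reduction, spec.spatial_kernel, rng=rng)
        self.conv3 = Conv(c256, c256, 3, 2, rng=rng)
        self.c2f7 = C2f(c256 + c512, c512, spec.depth(3), rng=rng)
        self.gam2 = GAM(c512, spec.gam_reduction, spec.spatial_kernel, rng=rng)
        self.conv4 = Conv(c512, c512, 3, 2, rng=rng)  # stride 2: aligns with SPPF scale
        self.c2f8 = C2f(c512 + c1024, c1024, spec.depth(1), rng=rng)
        # head reads (GAM1 @ s8, GAM2 @ s16, C2f8 @ s32)
        self.head = SegmentationHead(spec, (c256, c512, c1024), rng)

        self._backbone_names = ("conv1", "conv2", "c2f1", "gb1", "c2f2", "gb2",
                                "c2f3", "gb3", "c2f4", "sppf")

    # -- forward -----------------------------------------------------------
    def forward(self, x, training: bool = False) -> RawPredictions:
        x = ad.astensor(np.ascontiguousarray(x, dtype=ad.DTYPE))
        B, C, H, W = x.shape
        S = self.spec.input_size
        if (C, H, W) != (3, S, S):
            raise ValueError(f"expected (B, 3, {S}, {S}) input, got {x.shape}")
        t = training
        c2 = self.conv2(self.conv1(x, t), t)
        p2 = self.c2f1(c2, t)
        f2 = self.c2f2(self.gb1(p2, t), t)          # stride 8
        f3 = self.c2f3(self.gb2(f2, t), t)          # stride 16
        f4 = self.c2f4(self.gb3(f3, t), t)          # stride 32
        sp = self.sppf(f4, t)
        n5 = self.c2f5(ad.concat([ad.upsample_nearest2x(sp), f3], 1), t)
        n6 = self.c2f6(ad.concat([ad.upsample_nearest2x(n5), f2], 1), t)
        a1 = self.gam1(n6, t)                       # head input, stride 8
        n7 = self.c2f7(ad.concat([self.conv3(a1, t), n5], 1), t)
        a2 = self.gam2(n7, t)                       # head input, stride 16
        n8 = self.c2f8(ad.concat([self.conv4(a2, t), sp], 1), t)
        return self.head.forward_multi([a1, a2, n8], t)

    def __call__(self, x, training: bool = False) -> RawPredictions:
        return self.forward(x, training)

    def predict_raw(self, x) -> RawPredictions:
        """Inference forward without tape recording (deterministic)."""
        with ad.no_grad():
            return self.forward(x, training=False)

    # -- bookkeeping -------------------------------------------------------
    def backbone_param_count(self) -> int:
        return int(sum(p.data.size
                       for name in self._backbone_names
                       for p in getattr(self, name).parameters()))

    def wiring(self) -> list[tuple[str, str, tuple[str, ...]]]:
        """(node, kind, inputs) adjacency list of the layer graph."""
        dsname = "ghost_bottleneck" if self.ghost else "conv_s2"
        return [
            ("conv1", "conv_s2", ("input",)),
            ("conv2", "conv_s2", ("conv1",)),
            ("c2f1", "c2f", ("conv2",)),
            ("gb1", dsname, ("c2f1",)),
            ("c2f2", "c2f", ("gb1",)),
            ("gb2", dsname, ("c2f2",)),
            ("c2f3", "c2f", ("gb2",)),
            ("gb3", dsname, ("c2f3",)),
            ("c2f4", "c2f", ("gb3",)),
            ("sppf", "sppf", ("c2f4",)),
            ("upsample1", "upsample2x", ("sppf",)),
            ("concat1", "concat", ("upsample1", "c2f3")),
            ("c2f5", "c2f", ("concat1",)),
            ("upsample2", "upsample2x", ("c2f5",)),
            ("concat2", "concat", ("upsample2", "c2f2")),
            ("c2f6", "c2f", ("concat2",)),
            ("gam1", "gam", ("c2f6",)),
            ("conv3", "conv_s2", ("gam1",)),
            ("concat3", "concat", ("conv3", "c2f5")),
            ("c2f7", "c2f", ("concat3",)),
            ("gam2", "gam", ("c2f7",)),
            ("conv4", "conv_s2", ("gam2",)),
            ("concat4", "concat", ("conv4", "sppf")),
            ("c2f8", "c2f", ("concat4",)),
            ("head", "segmentation_head", ("gam1", "gam2", "c2f8")),
        ]

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        """Parameter archive (.npz) plus a JSON shape/spec manifest."""
        path = Path(path)
        state = self.state_dict()
        np.savez(path.with_suffix(".npz"), **state)
        manifest = {"spec": asdict(self.spec), "ghost": self.ghost,
                    "shapes": {k: list(v.shape) for k, v in state.items()}}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        spec_kw = manifest["spec"]
        spec_kw["strides"] = tuple(spec_kw["strides"])
        model = cls(ModelSpec(**spec_kw), ghost=manifest["ghost"])
        with np.load(path.with_suffix(".npz")) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model
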