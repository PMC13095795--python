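"""Encoder registry: ResNet18/50, VGG16, MobileNetV2 and a desk-scale tinycnn.

Each architecture is encoded explicitly (layer tables, block definitions) so
that parameter and multiply-accumulate accounting is a pure function of the
architecture, and so that `build_encoder` returns a working feature extractor
whose classification head is replaced by an identity: its output is the final
convolutional feature map, ready for GAP and view fusion.

Conventions
-----------
* Parameter counts use the ImageNet configuration (1000-class head attached),
  reported in millions to one decimal.
* "FLOPs" are reported as multiply-accumulates (MACs) over convolutional and
  fully connected layers for a single 224x224x3 forward pass, in giga-MACs to
  one decimal.  This is the convention under which the standard published
  figures for these backbones (1.8 G for ResNet18, 4.1 G for ResNet50,
  15.5 G for VGG16) are reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import (BatchNorm2d, Conv2d, Identity, Linear, MaxPool2d, Module,
                     ReLU, ReLU6, Sequential)

IMAGENET_CLASSES = 1000
INPUT_SIZE = 224


@dataclass
class BackboneSpec:
    name: str
    feature_dim: int
    final_map_size: int  # spatial side of the last conv output at 224 input
    pretrained: bool = False
    unfreeze_policy: str = "default"


_REGISTRY: dict[str, BackboneSpec] = {
    "resnet18": BackboneSpec("resnet18", 512, 7, unfreeze_policy="resnet_last_stage"),
    "resnet50": BackboneSpec("resnet50", 2048, 7, unfreeze_policy="resnet_last_stage"),
    "vgg16": BackboneSpec("vgg16", 512, 7, unfreeze_policy="vgg_all_conv"),
    "mobilenetv2": BackboneSpec("mobilenetv2", 1280, 7, unfreeze_policy="mnv2_last_block"),
    "tinycnn": BackboneSpec("tinycnn", 96, 56, unfreeze_policy="all"),
}


def available_backbones() -> list[str]:
    return sorted(_REGISTRY)


def get_spec(name: str, pretrained: bool = False) -> BackboneSpec:
    if name not in _REGISTRY:
        raise KeyError(f"unknown backbone {name!r}; registered: {available_backbones()}")
    spec = _REGISTRY[name]
    return BackboneSpec(spec.name, spec.feature_dim, spec.final_map_size,
                        pretrained, spec.unfreeze_policy)


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------


class ConvBNAct(Module):
    def __init__(self, cin, cout, k, stride=1, padding=0, groups=1, act="relu6"):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = ReLU6() if act == "relu6" else (ReLU() if act == "relu" else Identity())

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class BasicBlock(Module):
    expansion = 1

    def __init__(self, inplanes, planes, stride=1):
        super().__init__()
        self.conv1 = Conv2d(inplanes, planes, 3, stride, 1, bias=False)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, 1, 1, bias=False)
        self.bn2 = BatchNorm2d(planes)
        self.downsample = None
        if stride != 1 or inplanes != planes:
            self.downsample = Sequential(
                Conv2d(inplanes, planes, 1, stride, bias=False), BatchNorm2d(planes)
            )

    def forward(self, x):
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        shortcut = self.downsample(x) if self.downsample is not None else x
        return (out + shortcut).relu()


class Bottleneck(Module):
    expansion = 4

    def __init__(self, inplanes, planes, stride=1):
        super().__init__()
        self.conv1 = Conv2d(inplanes, planes, 1, bias=False)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, stride, 1, bias=False)
        self.bn2 = BatchNorm2d(planes)
        self.conv3 = Conv2d(planes, planes * 4, 1, bias=False)
        self.bn3 = BatchNorm2d(planes * 4)
        self.downsample = None
        if stride != 1 or inplanes != planes * 4:
            self.downsample = Sequential(
                Conv2d(inplanes, planes * 4, 1, stride, bias=False), BatchNorm2d(planes * 4)
            )

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        shortcut = self.downsample(x) if self.downsample is not None else x
        return (out + shortcut).relu()


class InvertedResidual(Module):
    def __init__(self, cin, cout, stride, expand_ratio):
        super().__init__()
        hidden = cin * expand_ratio
        self.use_res = stride == 1 and cin == cout
        layers = []
        if expand_ratio != 1:
            layers.append(ConvBNAct(cin, hidden, 1))
        layers.append(ConvBNAct(hidden, hidden, 3, stride, 1, groups=hidden))
        layers.append(Conv2d(hidden, cout, 1, bias=False))
        layers.append(BatchNorm2d(cout))
        self.block = Sequential(*layers)

    def forward(self, x):
        out = self.block(x)
        return out + x if self.use_res else out


# ---------------------------------------------------------------------------
# Architectures (encoders: head replaced by identity)
# ---------------------------------------------------------------------------


class ResNetEncoder(Module):
    def __init__(self, block, layers: list[int]):
        super().__init__()
        self.arch_name = "resnet18" if block is BasicBlock else "resnet50"
        self.conv1 = Conv2d(3, 64, 7, 2, 3, bias=False)
        self.bn1 = BatchNorm2d(64)
        self.maxpool = MaxPool2d(3, 2, 1)
        inplanes = 64
        stages = []
        for i, (planes, n) in enumerate(zip((64, 128, 256, 512), layers)):
            stride = 1 if i == 0 else 2
            blocks = [block(inplanes, planes, stride)]
            inplanes = planes * block.expansion
            blocks += [block(inplanes, planes) for _ in range(n - 1)]
            stages.append(Sequential(*blocks))
        self.layer1, self.layer2, self.layer3, self.layer4 = stages
        self.feature_dim = inplanes
        self.fc = Identity()  # native classifier head bypassed

    def forward(self, x):
        x = self.bn1(self.conv1(x)).relu()
        x = self.maxpool(x)
        for stage in (self.layer1, self.layer2, self.layer3, self.layer4):
            x = stage(x)
        return x


class VGG16Encoder(Module):
    CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
           512, 512, 512, "M", 512, 512, 512, "M"]

    def __init__(self):
        super().__init__()
        self.arch_name = "vgg16"
        layers = []
        cin = 3
        for v in self.CFG:
            if v == "M":
                layers.append(MaxPool2d(2, 2))
            else:
                layers += [Conv2d(cin, v, 3, 1, 1, bias=True), ReLU()]
                cin = v
        self.features = Sequential(*layers)
        self.feature_dim = 512

    def forward(self, x):
        return self.features(x)


class MobileNetV2Encoder(Module):
    SETTINGS = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
                (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1)]

    def __init__(self):
        super().__init__()
        self.arch_name = "mobilenetv2"
        feats = [ConvBNAct(3, 32, 3, 2, 1)]
        cin = 32
        for t, c, n, s in self.SETTINGS:
            for i in range(n):
                feats.append(InvertedResidual(cin, c, s if i == 0 else 1, t))
                cin = c
        feats.append(ConvBNAct(cin, 1280, 1))
        self.features = Sequential(*feats)
        self.feature_dim = 1280

    def forward(self, x):
        return self.features(x)


class TinyCNNEncoder(Module):
    """Fixed 3-block reference CNN for CPU-scale experiments.

    Three Conv-BN-ReLU blocks (16/32/96 channels) with 2x pooling after the
    first two; the final map is input_size/4 on a side with 96 channels
    (~47k params).
    """

    def __init__(self):
        super().__init__()
        self.arch_name = "tinycnn"
        self.features = Sequential(
            Conv2d(3, 16, 3, 1, 1, bias=False), BatchNorm2d(16), ReLU(), MaxPool2d(2),
            Conv2d(16, 32, 3, 1, 1, bias=False), BatchNorm2d(32), ReLU(), MaxPool2d(2),
            Conv2d(32, 96, 3, 1, 1, bias=False), BatchNorm2d(96), ReLU(),
        )
        self.feature_dim = 96

    def forward(self, x):
        return self.features(x)


def build_encoder(spec: BackboneSpec | str) -> Module:
    """Build a feature extractor whose output is the final conv feature map."""
    if isinstance(spec, str):
        spec = get_spec(spec)
    if spec.name not in _REGISTRY:
        raise KeyError(f"unknown backbone {spec.name!r}")
    if spec.pretrained:
        raise RuntimeError(
            "pretrained weights were requested but no ImageNet weights are "
            "available offline; pass pretrained=False or load a local "
            "checkpoint explicitly"
        )
    builders = {
        "resnet18": lambda: ResNetEncoder(BasicBlock, [2, 2, 2, 2]),
        "resnet50": lambda: ResNetEncoder(Bottleneck, [3, 4, 6, 3]),
        "vgg16": VGG16Encoder,
        "mobilenetv2": MobileNetV2Encoder,
        "tinycnn": TinyCNNEncoder,
    }
    return builders[spec.name]()


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------


def _head_layers(name: str) -> list[Linear]:
    """Native ImageNet classifier head used for accounting only."""
    if name in ("resnet18", "resnet50"):
        dim = 512 if name == "resnet18" else 2048
        return [Linear(dim, IMAGENET_CLASSES)]
    if name == "vgg16":
        return [Linear(512 * 7 * 7, 4096), Linear(4096, 4096),
                Linear(4096, IMAGENET_CLASSES)]
    if name == "mobilenetv2":
        return [Linear(1280, IMAGENET_CLASSES)]
    if name == "tinycnn":
        return [Linear(96, IMAGENET_CLASSES)]
    raise KeyError(f"unknown backbone {name!r}")


def count_parameters(name: str, head_classes: int | None = None) -> float:
    """Trainable parameters in millions (1 decimal), ImageNet head attached."""
    encoder = build_encoder(name)
    total = sum(p.data.size for p in encoder.parameters())
    for head in _head_layers(name):
        total += sum(p.data.size for p in head.parameters())
    return round(total / 1e6, 1)


def count_parameters_exact(name: str) -> int:
    encoder = build_encoder(name)
    total = sum(p.data.size for p in encoder.parameters())
    for head in _head_layers(name):
        total += sum(p.data.size for p in head.parameters())
    return int(total)


def _walk_macs(module: Module, shape: tuple) -> tuple[int, tuple]:
    """MACs of conv layers under `module` given input (C, H, W)."""
    if isinstance(module, Conv2d):
        return module.macs(shape), module.out_shape(shape)
    if isinstance(module, MaxPool2d):
        return 0, module.out_shape(shape)
    if isinstance(module, Sequential):
        total = 0
        for layer in module:
            m, shape = _walk_macs(layer, shape)
            total += m
        return total, shape
    if isinstance(module, ConvBNAct):
        return _walk_macs(module.conv, shape)
    if isinstance(module, BasicBlock):
        m1, s1 = _walk_macs(module.conv1, shape)
        m2, s2 = _walk_macs(module.conv2, s1)
        md = _walk_macs(module.downsample, shape)[0] if module.downsample else 0
        return m1 + m2 + md, s2
    if isinstance(module, Bottleneck):
        m1, s1 = _walk_macs(module.conv1, shape)
        m2, s2 = _walk_macs(module.conv2, s1)
        m3, s3 = _walk_macs(module.conv3, s2)
        md = _walk_macs(module.downsample, shape)[0] if module.downsample else 0
        return m1 + m2 + m3 + md, s3
    if isinstance(module, InvertedResidual):
        return _walk_macs(module.block, shape)
    if isinstance(module, ResNetEncoder):
        total, shape = _walk_macs(module.conv1, shape)
        shape = module.maxpool.out_shape(shape)
        for stage in (module.layer1, module.layer2, module.layer3, module.layer4):
            m, shape = _walk_macs(stage, shape)
            total += m
        return total, shape
    if isinstance(module, (VGG16Encoder, MobileNetV2Encoder, TinyCNNEncoder)):
        return _walk_macs(module.features, shape)
    return 0, shape  # BN, activations, identity


def count_macs_exact(name: str, input_size: int = INPUT_SIZE) -> int:
    encoder = build_encoder(name)
    conv_macs, _ = _walk_macs(encoder, (3, input_size, input_size))
    fc_macs = sum(h.in_features * h.out_features for h in _head_layers(name))
    return int(conv_macs + fc_macs)


def count_macs(name: str, input_size: int = INPUT_SIZE) -> float:
    """Giga multiply-accumulates (1 decimal) for one 224 forward pass."""
    return round(count_macs_exact(name, input_size) / 1e9, 1)


def backbone_table() -> "pandas.DataFrame":  # noqa: F821 - imported lazily
    """Accounting table over all registered backbones."""
    import pandas as pd

    rows = []
    for name in available_backbones():
        spec = _REGISTRY[name]
        rows.append({
            "backbone": name,
            "params_M": count_parameters(name),
            "macs_G": count_macs(name),
            "feature_dim": spec.feature_dim,
            "final_map": spec.final_map_size,
            "unfreeze_policy": spec.unfreeze_policy,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Differentiated unfreezing
# ---------------------------------------------------------------------------


def apply_unfreeze_policy(encoder: Module, name: str,
                          include_penultimate: bool = False) -> dict:
    """Partition encoder parameters into frozen and trainable groups.

    ResNets: only the final residual stage is unfrozen (optionally also the
    penultimate stage); VGG16: all conv layers are trainable; MobileNetV2:
    only the last feature block; tinycnn: everything.  Returns
    ``{"frozen": [(name, param)], "trainable": [(name, param)]}`` and sets the
    `trainable` flag on each parameter for the optimizer.
    """
    if getattr(encoder, "arch_name", None) != name:
        raise ValueError(
            f"unfreeze policy {name!r} applied to encoder built as "
            f"{getattr(encoder, 'arch_name', None)!r}"
        )
    named = encoder.named_parameters()

    def mark(pred):
        groups = {"frozen": [], "trainable": []}
        for pname, p in named:
            p.trainable = bool(pred(pname))
            groups["trainable" if p.trainable else "frozen"].append((pname, p))
        return groups

    if name in ("resnet18", "resnet50"):
        stages = ("layer4", "layer3") if include_penultimate else ("layer4",)
        return mark(lambda n: n.split(".")[0] in stages or n.startswith("fc"))
    if name == "vgg16":
        # all conv layers (weights and biases) trainable; nothing else exists
        conv_ids = {id(p) for m in encoder.modules() if isinstance(m, Conv2d)
                    for p in m.parameters()}
        return mark(lambda n: id(dict(named)[n]) in conv_ids)
    if name == "mobilenetv2":
        last = len(encoder.features.layers) - 1
        return mark(lambda n: n.startswith(f"features.layers.{last}."))
    if name == "tinycnn":
        return mark(lambda n: True)
    raise KeyError(f"no unfreeze policy registered for {name!r}")
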