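# orchardseg

Instance segmentation of fruit **and their stems** in orchard imagery,
built for robotic-harvesting pipelines where the gripper needs the stem,
not just the apple. The package implements a YOLOv8-style anchor-free
segmentation network with two architectural substitutions aimed at
efficient small-object segmentation:

- the backbone's stride-2 downsampling stages are **ghost bottlenecks** —
  residual blocks whose convolutions generate half their output channels
  with a cheap depthwise "ghost" operation (`X1 = Conv(X, c1 -> c2/r)`,
  `X2 = DWConv(X1, k, s)`, `X_out = [X1, X2]`), with squeeze-and-excitation
  channel gating `S = sigma(W2 . ReLU(W1 . GAP(X)))` inside the stride-2
  blocks — far fewer parameters than dense stride-2 convolutions at the
  same width;
- the neck carries **global attention modules** after each of its two
  finest fusion stages: channel attention
  `A_c = sigma(W2 . SiLU(W1 . GAP(X)))`, then spatial attention
  `A_s = sigma(W4 . SiLU(W3 . X_c))` over the channel-attended map
  `X_c = X . A_c`, output `X_s = X_c . A_s`.

The head predicts, per grid cell on strides 8/16/32, a discrete
distribution over 16 bins for each box-side distance (decoded by softmax
expectation), two class logits (apple, stem) and 32 mask-prototype
coefficients; instance masks are sigmoid-combined prototypes cropped to
the box. Training uses task-aligned assignment and the standard
four-component loss (CIoU box, BCE classification, distribution focal,
per-pixel mask BCE), SGD with momentum 0.937, weight decay 5e-4 and
initial learning rate 0.01, with early stopping on validation loss.

Because no public dataset ships with the package, a **synthetic orchard
scene generator** produces shaded elliptical apples, each with one thin
curved stem attached at its top boundary (occasionally partially hidden
behind the fruit), over varied backgrounds and illumination — with exact
polygon ground truth. Every pipeline stage is tested end to end against
it.

The whole network stack (reverse-mode autodiff, im2col convolutions,
batch normalisation, SGD) is implemented on numpy and runs on a single
CPU; the quarter-width "tiny" preset trains on synthetic scenes in
minutes.

## Worked example

```python
from orchardseg import OrchardSegmenter, SceneConfig
from orchardseg.synthetic import generate_samples

scenes = generate_samples(120, SceneConfig(), seed=7)  # 320-px labelled scenes
est = OrchardSegmenter.tiny(input_size=192, epochs=20, seed=0)
est.fit(scenes)
print(est.evaluate(generate_samples(10, SceneConfig(), seed=999)).table())
```

Twenty epochs on 120 scenes (~7 minutes on one CPU core) print:

```
[box]
Class        Precision    Recall    mAP@50  mAP@50-95
All              0.506     0.600     0.508      0.444
apple            0.952     1.000     0.995      0.882
stem             0.061     0.200     0.022      0.007
[mask]
Class        Precision    Recall    mAP@50  mAP@50-95
All              0.493     0.525     0.499      0.366
apple            0.952     1.000     0.995      0.732
stem             0.033     0.050     0.002      0.000
```

— apples (large, high-contrast) are essentially solved at this scale,
while stems (a few pixels wide) are just beginning to emerge; the longer
30-epoch run in the acceptance script below brings stem box mAP@50 to
roughly 0.26. Precision/recall are reported at each class's max-F1
confidence; AP uses 101-point interpolation over a confidence sweep.
`est.predict(images)` returns per-image `Detection` lists (class, score,
pixel box, boolean mask).

The same pipeline is scriptable from the shell:

```bash
orchardseg generate --n 200 --seed 1 --out data/
orchardseg split    --images data/images --labels data/labels --out splits/
orchardseg train    --images data/images --labels data/labels --out run/ \
                    --epochs 30 --input-size 192 --tiny
orchardseg predict  --model run/model --images data/images --out preds/
orchardseg eval     --predictions preds/predictions.json \
                    --images data/images --labels data/labels --out eval/
```

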