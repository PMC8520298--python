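# msaunet

Liver segmentation in CT slices with a multi-scale attention U-Net —
implemented end to end in numpy, with synthetic CT phantoms so the
whole pipeline runs on one CPU with no external data.

## Who this is for

Researchers and students in medical image analysis who want a fully
inspectable reference implementation of a U-shaped segmentation
network with multi-scale residual convolution, pooling-pyramid spatial
attention, attention-gated atrous spatial pyramid pooling, and
residual attention skip fusion — including the training protocol
(compound loss, LR-on-plateau, early stopping, flip TTA) — without a
deep-learning framework dependency. Everything down to the backward
passes is plain numpy and testable against finite differences.

## The model

The network maps a windowed CT slice to a per-pixel foreground
probability map:

- **Encoder**: `depth` stages of a *multi-scale residual block* (MSRB)
  followed by 2×2 max-pooling, filters doubling per stage. An MSRB
  fuses a 3×3 branch with a serial 3×3+3×3 branch (a 5×5 receptive
  field at 18C² instead of 25C² weights), adds a 1×1-projected
  residual, and applies DropBlock.
- **Bridge**: *attention atrous spatial pyramid pooling* (AASPP) —
  parallel convolutions at dilation rates 1/2/4/8, each gated by a
  *multi-scale attention module* (MSAM: a max-pool pyramid at scales
  2/4/8 fused coarse-to-fine into a sigmoid gate with the input's full
  shape).
- **Decoder**: `depth` *residual attention skip modules* (RASM) fusing
  each encoder skip with the upsampled decoder stream through two
  MSRBs, an MSAM, and two 1×1 residual projections.
- **Head**: 1×1 convolution + sigmoid.

Training minimizes `L = 0.5·L_bce + 1.0·L_dice`; evaluation thresholds
at 0.5 and reports DSC, IOU, precision and recall per case as
mean ± std. Ablation flags turn each block off, recovering a vanilla
U-Net. See `docs/methods.md` for the full specification and the design
decisions.

## Worked example

```bash
python examples/04_train_and_evaluate.py
```

generates 10 phantom cases (64×64, 8 slices each, 8:1:1 case split),
trains the full model (depth 2, base 8) for 15 epochs, and evaluates
the held-out case with flip TTA. Output from a run:

```
trained 15 epochs; val loss 0.869 -> 0.060
test dsc      : 0.790 +/- 0.000
test iou      : 0.653 +/- 0.000
test precision: 0.673 +/- 0.000
test recall   : 0.957 +/- 0.000
checkpoint saved to scratch/train_demo_model.npz
```

The validation loss falls from 0.87 to 0.06 in 15 epochs; on the one
held-out case the model finds 96% of organ pixels (recall) with a Dice
overlap of 0.79 — reasonable for a 15-epoch desk-scale run; longer
training pushes it higher (see the acceptance results below). The
other examples show phantom generation (`01`), the CT preprocessing
chain (`02`), and the blocks/ablation ladder (`03`):

```
U-Net         :   13617 parameters
U-Net + MSRB  :   15833 parameters
U-Net + AASPP :   51361 parameters
U-Net + RASM  :   41521 parameters
full model    :   81481 parameters
```

## Command line

The same pipeline is scriptable via a thin CLI:

```bash
msaunet generate -c config.yaml -o data/          # phantom dataset
msaunet preprocess -c config.yaml -d data -o prep # window + CLAHE
msaunet train -c config.yaml -d data -o run/      # checkpoint + history
msaunet evaluate -c config.yaml -d data -k run/checkpoint.npz -o eval --tta
msaunet predict -k run/checkpoint.npz -i vol.nii.gz -o pred/
```

`predict` accepts NIfTI volumes, DICOM series directories, or PNG
slices, and writes a binary mask PNG and a 16-bit probability PNG per
slice.

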