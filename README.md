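# decontrast

Remove the effect of a gadolinium-based contrast agent from T1-weighted
brain MRI by 3D image-to-image translation — and check that it worked where
it matters: in the tissue volumes that downstream neuroimaging tools
extract.

Clinical imaging archives mix contrast-enhanced (T1ce) and
non-contrast-enhanced (T1nce) T1 acquisitions.  Brain tissue segmentation
tools are validated on T1nce images; run them on T1ce and the gray-matter,
white-matter and CSF volumes they report are biased, which in turn biases
any volumetry-based computer-aided diagnosis.  `decontrast` trains 3D
U-Net-like generators (with residual, attention-gated or transformer
variants), optionally inside a patch-based conditional GAN, to map T1ce →
synthetic T1nce, and validates the translation on two tiers:

1. **Image similarity** inside a brain mask: MAE (%), PSNR (dB), SSIM,
   with paired t-tests and Bonferroni correction;
2. **Tissue-volume fidelity**: GM/WM/CSF segmentation of real T1nce vs
   T1ce vs synthetic T1nce, compared by TIV-normalised absolute/signed
   volume differences (AVD/VD, in cm³) and Dice overlap.

Because paired clinical data of this kind are access-restricted, the
package includes a seeded paired-phantom generator (nested-ellipsoid
anatomy, explicit enhancement model, three-axis 0/1/2 quality grading)
that lets the entire pipeline run end-to-end on one CPU in minutes.  The
neural-network stack (3D convolutions, normalisation layers, attention,
Adam, reverse-mode autodiff) is implemented on numpy inside
`decontrast.nn` and gradient-checked against finite differences.

## Worked example

Run the full desk-scale experiment (36 phantom subjects on a 32³ grid,
attention-gated generator, two training restarts of 60 epochs each,
~12 minutes on one CPU):

```bash
decontrast run-all --out runs/demo --seed 1
```

or from Python:

```python
from decontrast import io_cli
summary = io_cli.run_pipeline(io_cli.RunConfig(seed=1, out_dir="runs/demo"))
```

The run writes a BIDS-like phantom data set, trains the generator on the
medium/good-quality pairs, translates the held-out pairs and evaluates
both tiers.  With seed 1 it prints (abridged):

```json
{
 "n_train": 25, "n_test_good": 6, "n_test_low": 5,
 "similarity": {
  "t1nce_vs_t1ce":      {"mae_percent": 9.79, "psnr_db": 18.5, "ssim": 0.877},
  "t1nce_vs_synthetic": {"mae_percent": 7.00, "psnr_db": 20.4, "ssim": 0.930}
 },
 "segmentation": {
  "t1ce":      {"GM": 426.0, "WM": 464.7, "CSF": 89.9},
  "synthetic": {"GM":  67.9, "WM":  42.3, "CSF": 46.2}
 }
}
```

Reading: within the brain mask, the synthetic T1nce is much closer to the
real T1nce than the original T1ce is (lower MAE, higher PSNR/SSIM), and
the GM/WM/CSF volumes segmented from the synthetic image deviate far less
from the reference segmentation (AVD in cm³) than those segmented from the
T1ce — i.e. the contrast agent's segmentation bias is removed by the
translation.  Absolute numbers are phantom-scale; the *directions* of the
comparisons are the scientific content.

Per-pair tables (`similarity_per_pair.csv`, `segmentation_per_pair.csv`),
summary tables, the loss history and the trained generator checkpoint are
written next to `summary.json`.

## Library layout

| module | contents |
| --- | --- |
| `decontrast.phantom` | paired T1nce/T1ce phantom generator, enhancement and quality-degradation operators |
| `decontrast.preprocess` | min-max rescale, template crop, trilinear resample, quality labels, train/test split |
| `decontrast.generators` | Res-U-Net, Att-U-Net, Trans-U-Net builders (desk- and full-scale configs) |
| `decontrast.adversarial` | patch lattice, patch discriminator, LSGAN/log losses, soft labels, training loops |
| `decontrast.eval_similarity` | masked MAE/PSNR/SSIM, mask union, paired t-tests with Bonferroni |
| `decontrast.eval_segmentation` | stand-in GM/WM/CSF segmenter, binarisation, volumes, AVD/VD/Dice |
| `decontrast.io_cli` | NIfTI I/O, BIDS traversal, run configuration, pipeline, CLI |
| `decontrast.nn` | numpy autodiff tensor, 3D conv/norm/attention layers, Adam |

See `docs/methods.md` for the models, the phantom's assumptions, numerical
choices and known limitations.

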