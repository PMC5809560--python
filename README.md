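# shgtex

Quantitative texture morphometry for osteochondral second-harmonic-generation
(SHG) microscopy images: patch-based GLCM texture descriptors feeding a
bag-of-features (BoF) image classifier, plus a synthetic texture generator so
the whole pipeline is runnable and testable without microscope data.

## What it does

1. **GLCM texture parameters** (`shgtex.glcm`) — normalized gray-level
   co-occurrence matrices at d=1 and θ ∈ {0°, 45°, 90°, 135°}, with eight
   parameters: correlation, ASM, contrast, IDM, entropy, sum entropy,
   sum average and sum variance. Entropies use −Σ p log p (natural log);
   correlation is 0 when a marginal σ vanishes. Gray levels are linearly
   re-quantized (default 8 levels) because the 8×8-pixel ROIs are tiny.
2. **Patch descriptors** (`shgtex.features`) — 64×64-pixel patches on a
   regular grid (step 32 or 64 px) are split into the 8×8 grid of 8×8 ROIs;
   per (parameter, orientation) the 64 ROI values are histogrammed into 22
   fixed-range bins. Concatenating correlation/ASM/contrast/IDM over the four
   orientations gives the 352-dimensional vector
   `V = (h_Cor, h_ASM, h_Con, h_IDM)`.
3. **BoF classification** (`shgtex.bof`) — k-means codebook of visual words,
   nearest-centroid word assignment, normalized term vectors per image, and a
   linear SVM (one-vs-one for 3 classes). `evaluate_runs` implements the
   consecutive-run protocol: stratified folds, one fold tested per run,
   row-normalized confusion matrices averaged elementwise.
   `parameter_sweep` scans codebook size k and grid step g.
4. **Synthetic tissue textures** (`shgtex.synthetic`) — cartilage-like
   (homogeneous matrix with dark lacunae on a jittered ~15 µm lattice),
   bone-like (brighter, anisotropic fiber streaks) and fibrous-cartilage
   (oriented fiber band near the surface) images, simulated at 12-bit and
   converted through the same 12→8-bit path as acquired data. Deterministic
   per (params, seed).
5. **I/O and categorization** (`shgtex.io`) — 12→8-bit conversion
   (`floor(v/16)`), 512×512 sub-image cropping (regular 4×4 blocks or manual
   ROIs), and signal filtering (whole image: strictly more than 25 % of
   pixels above threshold; patch level: at least 25 %).

## CLI

```sh
shgtex simulate --out data/ --classes Cartilage,Bone --n-per-class 40 --seed 7
shgtex features --manifest data/manifest.csv --out features.csv --grid-step 64
shgtex train    --manifest data/manifest.csv --out model.joblib --k 20
shgtex predict  --model model.joblib data/bone_000.tif
shgtex evaluate --manifest data/manifest.csv --out cm.csv --k 20 --runs 4 --seed 7
shgtex sweep    --manifest data/manifest.csv --out sweep.csv --k 5,10,20,50,100 --grid-step 32,64
```

Every command writes a JSON run record (config + hash, seed, library
versions, kept/dropped counts) next to its output. Defaults can be
overridden with a YAML config (`--config run.yaml`); see
`shgtex.config.RunConfig` for the schema.

## Layout

```
src/shgtex/
  glcm.py       co-occurrence matrices + eight texture parameters
  features.py   patch grid, signal filter, 352-dim descriptor
  bof.py        codebook, term vectors, SVM, consecutive-run evaluation
  synthetic.py  tissue-like synthetic image generators
  io.py         GrayImage, bit-depth conversion, crops, TIFF/PNG, manifests
  config.py     YAML-backed run configuration
  cli.py        command-line entry points
tests/          unit + property tests; test_acceptance.py holds the
                acceptance criteria (oracle equivalence, grid counts,
                synthetic benchmarks, determinism)
scripts/acceptance.py
```
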