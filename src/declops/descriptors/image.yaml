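version: "1"
ops:
  - names: [filter.gauss]
    type: computer
    source: "declops.image_ops:gauss"
    description: "Separable Gaussian blur; kernel half-width ceil(4*sigma), mirror border."
    parameters:
      - {name: input, type: dense-image, io: input, description: "image to blur"}
      - {name: sigma, type: real, io: input, description: "Gaussian standard deviation (pixels)"}
      - {name: output, type: dense-image, io: container}

  - names: [filter.dog]
    type: function
    source: "declops.image_ops:dog"
    description: "Difference of Gaussians band-pass: gauss(sigma1) - gauss(sigma2)."
    parameters:
      - {name: input, type: dense-image, io: input}
      - {name: sigma1, type: real, io: input}
      - {name: sigma2, type: real, io: input}
      - {name: out, type: dense-image, io: output}
    dependencies:
      - {slot: gauss1, name: filter.gauss, type: function, in: [dense-image, real], out: dense-image}
      - {slot: gauss2, name: filter.gauss, type: function, in: [dense-image, real], out: dense-image}
      - {slot: sub, name: math.sub, type: function, in: [dense-image, dense-image], out: dense-image}

  - names: [image.histogram]
    type: function
    source: "declops.image_ops:histogram"
    description: "Counting histogram; floor bin assignment, last bin right-closed."
    parameters:
      - {name: input, type: dense-image, io: input}
      - {name: bins, type: integer, io: input, optional: true, default: 256}
      - {name: out, type: histogram, io: output}

  - names: [threshold.otsu]
    type: function
    source: "declops.image_ops:otsu"
    description: "Threshold maximizing between-class variance over a 256-bin histogram."
    parameters:
      - {name: input, type: dense-image, io: input}
      - {name: out, type: threshold-result, io: output}
    dependencies:
      - {slot: histogram, name: image.histogram, type: function, in: [dense-image, integer], out: histogram}

  - names: [filter.fft]
    type: function
    source: "declops.image_ops:fft"
    description: "DFT of the mirror-padded image; fast pads axes to {2,3,5,7}-smooth lengths."
    parameters:
      - {name: input, type: dense-image, io: input}
      - {name: fftType, type: text, io: input, description: "real_to_complex"}
      - {name: borderSize, type: integer, io: input, optional: true, default: 0,
         description: "per-axis mirror padding"}
      - {name: fast, type: boolean, io: input, optional: true, default: true,
         description: "round padded axes up to fast sizes"}
      - {name: out, type: complex-grid, io: output}

  - names: [stats.pnorm]
    type: function
    source: "declops.image_ops:pnorm"
    description: "Standard normal CDF of a scalar."
    parameters:
      - {name: x, type: real, io: input}
      - {name: out, type: real, io: output}

  - names: [stats.pnorm]
    type: function
    source: "declops.image_ops:pnorm_image"
    description: "Standard normal CDF applied element-wise to a z-score image."
    parameters:
      - {name: x, type: dense-image, io: input}
      - {name: out, type: dense-image, io: output}

  - names: [coloc.sigMask]
    type: function
    source: "declops.image_ops:sig_mask"
    description: "Binary mask of significantly colocalized pixels (one-sided upper tail)."
    parameters:
      - {name: zscores, type: dense-image, io: input}
      - {name: alpha, type: real, io: input, optional: true, default: 0.05}
      - {name: out, type: dense-image, io: output}
    dependencies:
      - {slot: pnorm, name: stats.pnorm, type: function, in: [dense-image], out: dense-image}

  - names: [fixtures.synthetic_image]
    type: function
    source: "declops.image_ops:synthetic_image"
    description: "Seeded sum of Gaussian spots plus Gaussian noise (test fixture)."
    parameters:
      - {name: shape, type: int-list, io: input}
      - {name: n_spots, type: integer, io: input}
      - {name: spot_sigma, type: real, io: input}
      - {name: noise_sd, type: real, io: input}
      - {name: seed, type: integer, io: input}
      - {name: out, type: dense-image, io: output}
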