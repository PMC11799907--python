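network:
  in_channels: 1
  stage_widths:
  - 8
  - 16
  - 44
  - 56
  - 128
  - 392
  - 88
  - 128
  - 32
  - 16
  - 8
  K: 4
  dyconv_kernel: 3
  dw_kernel: 7
  expansion: 4
  se_enabled: true
  fem_enabled: true
  se_reduction: 4
  upsample_mode: channel_then_size
  trans_kernel: 4
  conv_mode: static
  threshold: 0.5
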