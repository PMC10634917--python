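n_frames: 30000
pixel_size_nm: 160.0
target_id: bassoon
units: nm
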