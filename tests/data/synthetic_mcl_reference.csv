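label,value
blank_co3,0.21
blank_co5,0.45
blank_co7,0.74
blank_co9,1.19
blank_co11,1.78
vip109_co3,0.25
vip109_co5,0.52
vip109_co7,0.95
vip109_co9,1.52
vip109_co11,2.28
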