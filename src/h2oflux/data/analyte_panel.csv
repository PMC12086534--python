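name,formula,n_exchangeable,precursor_mz,product_mz
T-CA,C26H44NO7S,14,514.2,80.0
T-aMCA,C26H44NO7S,14,514.2,80.0
T-bMCA,C26H44NO7S,10,514.2,80.0
T-CDCA,C26H44NO6S,18,498.2,80.0
T-DCA,C26H44NO6S,10,498.2,80.0
palmitate,C16H31O2,22,255.2,
cholesterol-fragment,C18H31,20,247.2,
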