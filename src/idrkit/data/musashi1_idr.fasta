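>MSI1_IDR O43347 Musashi-1 C-terminal intrinsically disordered region, residues 194-362
GSARGRSRVMPYGMDAFMLGIGMLGYPGFQATTYASRSYTGLAPGYTYQFPEFRVERTPL
PSAPVLPELTAIPLTAYGPMAAAAAAAAVVRGTGSHPWTMAPPPGSTPSRTGGFLGTTSP
GPMAELYGAANQDSGVSSYISAASPAPSTGFGHSLGGPLIATAFTNGYH
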