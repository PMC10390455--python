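# Published nuclear S-values (Gy/Bq/s) for the 225Ac chain from a Geant4-DNA
# Monte Carlo study of the MIRD single cell (10 um cell / 8 um nucleus) and a
# 13-cell cluster, with the percent difference each value carries relative to
# MIRDcell v3.10.  MIRDcell comparison values are reconstructed as
# S_mirdcell = S / (1 + pct/100).
target,nuclide,compartment,S,pct_diff_vs_mirdcell
self,Ac-225,cell_surface,4.84e-2,-4.4
self,Ac-225,cytoplasm,6.29e-2,-5.9
self,Ac-225,nucleus,1.40e-1,-4.5
self,Ac-225,whole_cell,1.02e-1,-5.1
self,Fr-221,cell_surface,4.36e-2,-7.3
self,Fr-221,cytoplasm,5.87e-2,-5.7
self,Fr-221,nucleus,1.30e-1,-4.8
self,Fr-221,whole_cell,9.64e-2,-3.6
self,At-217,cell_surface,4.09e-2,-4.9
self,At-217,cytoplasm,5.42e-2,-4.8
self,At-217,nucleus,1.18e-1,-5.5
self,At-217,whole_cell,8.73e-2,-4.8
self,Bi-213,cell_surface,1.22e-3,-3.6
self,Bi-213,cytoplasm,1.49e-3,-12.2
self,Bi-213,nucleus,3.62e-3,-6.4
self,Bi-213,whole_cell,2.64e-3,-6.0
self,Po-213,cell_surface,3.31e-2,-12.1
self,Po-213,cytoplasm,4.48e-2,-10.1
self,Po-213,nucleus,1.04e-1,-5.6
self,Po-213,whole_cell,7.62e-2,-5.5
self,Tl-209,cell_surface,1.91e-4,-48.8
self,Tl-209,cytoplasm,2.48e-4,-56.2
self,Tl-209,nucleus,5.62e-4,-70.9
self,Tl-209,whole_cell,4.13e-4,-67.3
self,Pb-209,cell_surface,2.70e-4,8.5
self,Pb-209,cytoplasm,3.69e-4,8.8
self,Pb-209,nucleus,8.51e-4,8.1
self,Pb-209,whole_cell,6.17e-4,8.6
self,Total,cell_surface,1.67e-1,-6.9
self,Total,cytoplasm,2.21e-1,-6.5
self,Total,nucleus,4.94e-1,-5.0
self,Total,whole_cell,3.64e-1,-4.7
cross,Ac-225,cell_surface,1.29e-2,-1.8
cross,Ac-225,cytoplasm,1.21e-2,-5.3
cross,Ac-225,nucleus,1.10e-2,-9.7
cross,Ac-225,whole_cell,1.19e-2,-4.9
cross,Fr-221,cell_surface,1.21e-2,-0.3
cross,Fr-221,cytoplasm,1.16e-2,-1.9
cross,Fr-221,nucleus,1.04e-2,-7.3
cross,Fr-221,whole_cell,1.02e-2,-10.9
cross,At-217,cell_surface,1.01e-2,-7.9
cross,At-217,cytoplasm,1.00e-2,-6.3
cross,At-217,nucleus,9.70e-3,-5.8
cross,At-217,whole_cell,9.37e-3,-10.7
cross,Bi-213,cell_surface,3.34e-4,3.5
cross,Bi-213,cytoplasm,2.75e-4,-12.7
cross,Bi-213,nucleus,2.77e-4,-7.5
cross,Bi-213,whole_cell,2.84e-4,-7.5
cross,Po-213,cell_surface,9.38e-3,-1.5
cross,Po-213,cytoplasm,8.91e-3,-4.2
cross,Po-213,nucleus,8.23e-3,-6.7
cross,Po-213,whole_cell,8.25e-3,-8.9
cross,Tl-209,cell_surface,4.66e-5,-44.3
cross,Tl-209,cytoplasm,4.29e-5,-46.8
cross,Tl-209,nucleus,4.47e-5,-40.1
cross,Tl-209,whole_cell,4.43e-5,-44.6
cross,Pb-209,cell_surface,6.27e-5,8.3
cross,Pb-209,cytoplasm,6.07e-5,7.8
cross,Pb-209,nucleus,5.72e-5,8.0
cross,Pb-209,whole_cell,5.77e-5,5.7
cross,Total,cell_surface,4.46e-2,-2.7
cross,Total,cytoplasm,4.28e-2,-4.5
cross,Total,nucleus,3.95e-2,-7.5
cross,Total,whole_cell,3.99e-2,-8.7
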