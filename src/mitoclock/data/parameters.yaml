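# Rate constants (per min), Michaelis constants and total concentrations
# (dimensionless a.u.) for the four cell-cycle models.  Each value carries a
# provenance tag naming where it is fixed: the shared parameter table
# ("table"), a figure-caption constant ("fig<N> caption"), or the global
# totals note attached to the table ("totals note").
model1:
  ksy_cycb:   {value: 0.04, source: table}
  kde1_cycb:  {value: 0.02, source: table}
  kde2_cycb:  {value: 0.4,  source: table}
  kph_gwl:    {value: 0.2,  source: table}   # intermediary-kinase activation
  kdp1_gwl:   {value: 0.08, source: table}
  kph_apc:    {value: 0.2,  source: table}
  kdp_apc:    {value: 0.08, source: table}
  Jph_kin:    {value: 0.01, source: fig2 caption}
  Jdp_kin:    {value: 0.01, source: fig2 caption}
  Jph_apc:    {value: 0.1,  source: fig2 caption}
  Jdp_apc:    {value: 0.1,  source: fig2 caption}
  PP:         {value: 1.0,  source: fig2 caption}
  Kin_tot:    {value: 1.0,  source: fig2 caption}
  APC_tot:    {value: 1.0,  source: fig2 caption}

model2:
  ksy_cycb:   {value: 0.04, source: table}
  kde1_cycb:  {value: 0.02, source: table}
  kde2_cycb:  {value: 2.0,  source: table}
  kph_gwl:    {value: 0.1,  source: table}
  kdp1_gwl:   {value: 0.2,  source: table}
  kph_apc:    {value: 1.0,  source: table}
  kdp_apc:    {value: 20.0, source: table}
  kph_ensa:   {value: 0.2,  source: table}
  kcat:       {value: 0.1,  source: table}
  kas1:       {value: 10.0, source: table}
  kdi1:       {value: 0.1,  source: table}
  Km_tqssa:   {value: 0.0008, source: fig3 caption}
  deUb:       {value: 0.75, source: fig3 caption}
  PP:         {value: 1.0,  source: totals note}
  Gwl_tot:    {value: 1.0,  source: totals note}
  APC_tot:    {value: 1.0,  source: totals note}
  B55_tot:    {value: 1.0,  source: totals note}
  ENSA_tot:   {value: 4.0,  source: totals note}
  Cdc20_tot:  {value: 1.0,  source: totals note}

model3:
  ksy_cycb:   {value: 0.04, source: table}
  kde1_cycb:  {value: 0.02, source: table}
  kde2_cycb:  {value: 0.5,  source: table}
  kph_gwl:    {value: 2.0,  source: table}
  kdp1_gwl:   {value: 2.0,  source: table}
  kdp2_gwl:   {value: 20.0, source: table}
  kph_apc:    {value: 1.0,  source: table}
  kdp_apc:    {value: 20.0, source: table}
  kph_ensa:   {value: 1.0,  source: table}
  kcat:       {value: 1.0,  source: table}
  kas1:       {value: 10.0, source: table}
  kdi1:       {value: 0.1,  source: table}
  Km_tqssa:   {value: 0.0026, source: fig4 caption}
  deUb:       {value: 0.5,  source: fig4 caption}
  PP:         {value: 1.0,  source: totals note}
  Gwl_tot:    {value: 1.0,  source: totals note}
  APC_tot:    {value: 1.0,  source: totals note}
  B55_tot:    {value: 1.0,  source: totals note}
  ENSA_tot:   {value: 4.0,  source: totals note}
  Cdc20_tot:  {value: 1.0,  source: totals note}

model4:
  ksy_cycb:   {value: 0.04, source: table}
  kde1_cycb:  {value: 0.02, source: table}
  kde2_cycb:  {value: 1.0,  source: table}
  kph_gwl:    {value: 2.0,  source: table}
  kdp1_gwl:   {value: 0.5,  source: table}
  kdp2_gwl:   {value: 20.0, source: table}
  kph_apc:    {value: 1.0,  source: table}
  kdp_apc:    {value: 20.0, source: table}
  kph_ensa:   {value: 1.0,  source: table}
  kcat:       {value: 1.0,  source: table}
  kas1:       {value: 10.0, source: table}
  kdi1:       {value: 0.1,  source: table}
  kph1_cdk:   {value: 0.02, source: table}
  kph2_cdk:   {value: 2.0,  source: table}
  kdp1_cdk:   {value: 0.2,  source: table}
  kdp2_cdk:   {value: 2.0,  source: table}
  Km_tqssa:   {value: 0.0026, source: fig5 caption}
  deUb:       {value: 0.5,  source: fig5 caption}
  CAP:        {value: 0.3,  source: fig5 caption}
  PP:         {value: 1.0,  source: totals note}
  Gwl_tot:    {value: 1.0,  source: totals note}
  APC_tot:    {value: 1.0,  source: totals note}
  B55_tot:    {value: 1.0,  source: totals note}
  ENSA_tot:   {value: 4.0,  source: totals note}
  Cdc20_tot:  {value: 1.0,  source: totals note}
  Wee1_tot:   {value: 1.0,  source: totals note}
  Cdc25_tot:  {value: 1.0,  source: totals note}
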